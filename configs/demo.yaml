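# Demo pipeline configuration: 3 lines x 2 tagged individuals, EcoRI+TaqI
# AFLP with a 200-400 bp gel cut (leakage over 100-500 bp), 454-style reads,
# and a GsuI-trimmed non-amplified cDNA library.
seed: 1

design:
  n_lines: 3
  individuals_per_line: 2
  genome_length: 300000
  snp_rate: 0.002
  line_specific_fraction: 0.3

size_selection:
  low: 200
  high: 400
  leak_prob: 0.1
  ext_low: 100
  ext_high: 500

read_model:
  mean_len: 246
  len_sd: 40
  sub_rate: 0.002
  hp_indel_base: 0.0005
  hp_slope: 2.0
  chimera_rate: 0.02

reads:
  n_aflp: 6000
  n_cdna: 1500

cdna:
  n_transcripts: 300
  mean_len: 800
  polya_mean: 50
  uncut_prob: 0.02

demux:
  min_len: 120
  max_primer_mm: 2

cluster:
  min_identity: 0.95
  min_overlap: 50
  min_allele_reads: 2
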