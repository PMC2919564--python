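# Methods

## Scope and model

The package treats two reduced-representation library designs as explicit,
testable procedures: individually tagged AFLP genomic fragments, and
GsuI-trimmed cDNA prepared without PCR amplification. Every analysis stage
(demultiplexing, polyA QC, clustering, SNP-candidate detection,
representation statistics) runs on synthetic data whose generator emulates
the wet-lab protocol, so each stage can be scored against a per-read truth
table instead of unavailable run data. Run-scale outcomes of the original
study (total read counts, contig inventories, SNP totals) depend on the
deposited sequencing data and are treated as format and definition anchors
only; the quantities this package reproduces exactly are the run's printed
worked-example statistics, which are pure arithmetic on printed inputs.

## Sequence primitives

Coordinates are 0-based, half-open. A restriction enzyme is its IUPAC
recognition site plus top/bottom-strand cut offsets measured from the 3′
end of the site (EcoRI `G^AATTC` → cut_top −5; TaqI `T^CGA` → cut_top −3;
GsuI `CTGGAG` → 16/14, a 2-nt 3′ overhang). Offsets are configuration
data, not hard-coded. Digestion cuts at every unmasked site of every
enzyme simultaneously; fragments are emitted on the top strand only
(sequencing reads are single-stranded observables; the bottom-strand
offset is kept solely for overhang geometry). Cut positions falling
outside the molecule are skipped and logged; coincident cuts of two
enzymes would create an empty fragment, which is suppressed and logged.
Hemimethylation protection is modelled positionally: a mask lists site
positions exempt from cleavage, without simulating methyl chemistry.

## Synthetic panel and tagged amplicons

One random ancestral sequence is mutated into lines and individuals by
substitutions only, so coordinates stay ancestral and truth bookkeeping is
exact. Variant positions are sampled at `snp_rate` per bp; a configurable
fraction is *fixed* in exactly one line (all four haplotypes), the rest
segregate at a uniform random frequency, redrawn if the carrier set would
be empty or confined to a single line (which would silently corrupt the
truth flags). Defaults: 3 lines × 2 diploid individuals, 300 kb genome,
`snp_rate` 0.002, line-specific fraction 0.3. The genome length is chosen
so the 200–400 bp window holds on the order of fifty Eco–Taq loci — a
desk-scale image of a reduced representation; the SNP rate is in the range
expected between divergent selection lines. Neither is tuned to any output.

Amplicons are built per haplotype as
`tagged_primer(left end) + insert + revcomp(tagged_primer(right end))`,
both primers carrying the individual's 4-nt tag. The observable flank is
exactly the tagged preamplification primer: ligated adapter sequence
upstream of the primer is never read after preamplification, and the
5′-phosphate is ligation chemistry only. Only Eco–Taq fragments amplify by
default (classic AFLP suppression of same-end fragments); Eco–Eco/Taq–Taq
retention is a configuration switch, since both primer families are tagged
and the design leaves their amplification open. Gel size selection keeps
[200, 400] bp always, retains lengths in the extended [100, 500] bp window
with `leak_prob` (default 0.1) independently per molecule, and nothing
outside it.

## cDNA synthesis and GsuI trimming

A transcript must end in a poly(A) run of ≥ 16 nt (the primer's T tract);
shorter tails yield no product, as with the anchored primer. The
first-strand product is `GAGAGAGAGACTGGAG + T16 + revcomp(body)` — the VN
anchor pairs with the last two non-A bases, so the T tract length is fixed
at 16 regardless of the true tail length. GsuI cuts 16 nt downstream of
the primer-borne `CTGGAG`, i.e. exactly at the far edge of the T tract:
the trimmed double-stranded product is `revcomp(body)` with the VN
junction as its first two bases (overhang fill-in assumed). Internal
`CTGGAG` sites are never cut (hemimethylation). With probability
`uncut_prob` (default 0.02) digestion fails and the product keeps the full
primer; these are the molecules the residual-primer QC must find. PolyA
tail lengths are geometric with mean 50 nt; transcripts carry log-normal
expression weights and no PCR duplication is simulated — the protocol's
point is that read frequency is expression.

## Read simulation

454-style single-end reads: length normal (mean 246 bp, sd 40, floor 30),
template strand equiprobable, read taken from one template end.
Substitutions occur per base at `sub_rate` (default 0.002). Indels are
homopolymer-driven: each maximal run of length L suffers a one-base
insertion or deletion (equiprobable) with probability
`min(1, hp_indel_base · (1 + hp_slope · (L − 1)))`; defaults
`hp_indel_base` 5·10⁻⁴ and `hp_slope` 2 keep single bases nearly
error-free while a 16-mer T tract fails at ~1.6% — the qualitative 454
signature the GsuI trim exists to avoid. With probability `chimera_rate`
(default 0.02) a read splices the 5′ part of one fragment to the 3′ part
of another, so a chimera of two individuals displays two different valid
tags, the signature the dual-end tagging detects. Every read carries a
truth record: source individual and fragment, chimera flag, and each
planted-variant site it covers together with the allele it carries. Reads
are emitted as Phred+33 FASTQ at constant Q30: quality strings are not
modelled and no stage reads them.

## Demultiplexing

Reads strictly longer than 120 bp are scanned at both ends (3′ via the
reverse complement) for a 4-nt tag followed by a family-constant primer
core. The tag is matched exactly while the core tolerates
`max_primer_mm` (default 2) substitutions: the study's notion of "false
tags" — 4-mers next to a valid core that are not in the designed set —
requires the tag to be read literally. Family ties resolve to Eco and are
logged. The default scan is a Hamming comparison at offset 0; an
edit-distance mode (edlib) exists for real reads with indels near the
primer. Categories partition every input read; a read with any
invalid-tag hit is `false_tag` even if its other end is valid, keeping
`double_diff` a pure two-valid-tags (chimera) signature that the truth
table can score separately. Trimming removes the detected tag+core spans.

## Clustering and SNP candidates

Trimmed double-same-tag reads are clustered by greedy star clustering:
reads sorted by (length desc, sequence asc, id asc); each read joins the
first seed whose best ungapped-offset identity reaches `min_identity`
(default 0.95) over ≥ `min_overlap` (default 50) bases, both strands
tested, else founds a new seed. Ungapped alignment is deliberate — 454
indels sit in homopolymers, and the rule is exactly checkable against an
exhaustive all-pairs oracle, which the test suite does on 50-read inputs.
Candidate placements are found through a 12-mer index and verified
exactly; at pipeline identity levels a qualifying placement always shares
a 12-mer with the seed. Depth-1 clusters are singlets; consensus is
per-column majority with lexicographic tie-break. All thresholds are this
package's declared procedure: the original study does not state its
assembler or criteria.

A consensus column is a SNP candidate iff exactly two alleles each have
≥ `min_allele_reads` (default 2) supporting reads and the supporters span
≥ 2 distinct individuals; columns with ≥ 3 supported alleles are skipped
as alignment artefacts (logged). Reference is the consensus allele;
per-individual allele depths come from each member's demux tag. A
candidate is *line-specific* when its alternate allele is confined to the
individuals of exactly one line — an observational statement about the
sampled reads, which is what the tagged design makes available. Candidates
are written as a sites-only VCF (cluster consensi as contigs, 1-based POS,
per-individual depths and a LINE_SPECIFIC flag in INFO) plus a TSV twin.

## Truth-based evaluation

Demultiplexer accuracy is the fraction of double-same-tag reads whose tag
maps to the truth individual. A planted variant is *recoverable* when each
allele covers its site in ≥ `min_allele_reads` clustered non-chimeric
reads; it is *recovered* when a candidate matches it by allele pair and
flanking context (±15 consensus columns against the ancestral
neighbourhood, either orientation, ≥ 80% identity excluding the site
itself — reads are ungapped copies, so a true candidate's context is
near-exact). A line-specific flag is a *false positive* only when it
contradicts the truth table for the reads the caller used: no matching
planted variant, alt-supporting reads from more than one true line, or a
tag-derived line differing from the true one. A flag whose alt reads
genuinely all came from one line (sampling) or whose ref/alt polarity the
consensus majority flipped is not an attribution error.

## Representation statistics

Headline percentages (double-tag rate, same-tag rate and complement,
untagged rate, tag-bearing share) are pure functions of the demux totals,
printed to 1 decimal with round-half-up. The per-tag proportion column
uses largest-remainder (sum-preserving) rounding: printed composition
tables total exactly 100.0, and plain rounding misses one printed value by
0.1. The per-sequence tagging efficiency (tag-bearing / analysed, 99.8%
for the published totals) is the only efficiency the run totals support; a
higher printed figure circulating for this run is not derivable from them
and is not reproduced.

## Determinism and problem sizes

One top-level seed drives every stage through independently spawned child
streams (all below 2³¹); the same configuration yields byte-identical
FASTQ, TSV, VCF and JSON outputs. Default desk-scale sizes — 300 kb
genome, ~500 retained amplicons, 6,000 AFLP reads, 300 transcripts, 1,500
cDNA reads — keep a full pipeline run in seconds while leaving every
stage's statistics well-resolved; evaluation runs use up to 20,000 reads
(~20× per-individual contig depth) and 10,000-read demux scoring.

## What the generator does and does not show

The simulator reproduces the protocol's *structure*: tag geometry at both
read ends, restriction-defined fragment boundaries, gel leakage, the exact
GsuI/oligo(dT) trimming geometry, homopolymer-biased indels, chimeras, and
line-structured variation. It does not model flowgram space or realistic
quality values, PCR amplification bias (absent by design on the cDNA
side; not modelled for AFLP preamplification), repeat families or
paralogy (the ancestor is i.i.d. random, so clusters are never confounded
by near-identical loci), GC effects on gel migration, or real 454 length
distributions beyond the stated mean. Passing tests therefore demonstrate
correctness of the analysis logic under the protocol's idealised geometry,
not performance on repetitive real genomes.

## Known limitations

- Ungapped clustering fragments loci whose reads carry early indels;
  at the default error rates this costs depth, not correctness, and an
  optional edit-distance demux mode mitigates the primer side only.
- A locus longer than twice the read length minus `min_overlap` yields two
  end-anchored clusters; depth summaries count them separately.
- `min_allele_reads` is an absolute threshold: at depths far above ~50×,
  substitution errors can produce spurious candidates, which the
  line-specific evaluation tolerates but a production caller would filter
  by fraction.
- The 8-tag panel supports at most 8 individuals; larger designs need a
  longer tag set supplied via the panel TSV.
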