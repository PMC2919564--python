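"""End-to-end pipeline: simulate -> demux -> polyA QC -> cluster -> report.

A single JSON/YAML config (one top-level seed) drives every stage; all
stage randomness is derived from that seed, so the same config produces
byte-identical outputs.  Artifacts are plain text: FASTA/FASTQ, TSV tables,
a sites-only VCF and a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster_snp, demux, evaluate, io, polya_qc, report
from .core_seq import DEFAULT_ENZYMES, RestrictionEnzyme
from .panel import TagPrimerPanel, table1_panel
from .protocol_sim import (PanelDesign, ReadModel, SizeSelection,
                           make_aflp_amplicons, make_cdna_library,
                           simulate_panel, simulate_reads,
                           simulate_transcripts, size_select)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


#: Config schema: section -> allowed keys (None = scalar).
_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "design": {"n_lines", "individuals_per_line", "genome_length", "snp_rate",
               "line_specific_fraction"},
    "size_selection": {"low", "high", "leak_prob", "ext_low", "ext_high"},
    "read_model": {"mean_len", "len_sd", "sub_rate", "hp_indel_base",
                   "hp_slope", "chimera_rate"},
    "reads": {"n_aflp", "n_cdna"},
    "cdna": {"n_transcripts", "mean_len", "polya_mean", "uncut_prob"},
    "demux": {"min_len", "max_primer_mm", "include_single_tag"},
    "cluster": {"min_identity", "min_overlap", "min_allele_reads"},
    "enzymes": None,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    design: PanelDesign = field(default_factory=PanelDesign)
    size_selection: SizeSelection = field(default_factory=SizeSelection)
    read_model: ReadModel = field(default_factory=ReadModel)
    n_reads_aflp: int = 6000
    n_reads_cdna: int = 1500
    n_transcripts: int = 300
    cdna_mean_len: int = 800
    cdna_polya_mean: int = 50
    uncut_prob: float = 0.02
    demux_min_len: int = 120
    demux_max_mm: int = 2
    include_single_tag: bool = False
    min_identity: float = 0.95
    min_overlap: int = 50
    min_allele_reads: int = 2
    enzymes: list[RestrictionEnzyme] = field(
        default_factory=lambda: [DEFAULT_ENZYMES["EcoRI"], DEFAULT_ENZYMES["TaqI"]])

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("missing config keys: ['seed']")
        for section, allowed in _SCHEMA.items():
            if allowed is None or section not in raw:
                continue
            bad = set(raw[section]) - allowed
            if bad:
                raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
        seed = int(raw["seed"])
        design = PanelDesign(seed=seed, **raw.get("design", {}))
        sel = SizeSelection(**raw.get("size_selection", {}))
        model = ReadModel(seed=seed, **raw.get("read_model", {}))
        enz = [RestrictionEnzyme(**e) for e in raw.get("enzymes", [])] or None
        cdna = raw.get("cdna", {})
        reads = raw.get("reads", {})
        dmx = raw.get("demux", {})
        clu = raw.get("cluster", {})
        cfg = cls(seed=seed, design=design, size_selection=sel, read_model=model,
                  n_reads_aflp=int(reads.get("n_aflp", 6000)),
                  n_reads_cdna=int(reads.get("n_cdna", 1500)),
                  n_transcripts=int(cdna.get("n_transcripts", 300)),
                  cdna_mean_len=int(cdna.get("mean_len", 800)),
                  cdna_polya_mean=int(cdna.get("polya_mean", 50)),
                  uncut_prob=float(cdna.get("uncut_prob", 0.02)),
                  demux_min_len=int(dmx.get("min_len", 120)),
                  demux_max_mm=int(dmx.get("max_primer_mm", 2)),
                  include_single_tag=bool(dmx.get("include_single_tag", False)),
                  min_identity=float(clu.get("min_identity", 0.95)),
                  min_overlap=int(clu.get("min_overlap", 50)),
                  min_allele_reads=int(clu.get("min_allele_reads", 2)))
        if enz:
            cfg.enzymes = enz
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(raw or {})


@dataclass
class PipelineResult:
    config: PipelineConfig
    summary: dict
    out_dir: Path | None


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent per-stage streams, all below 2**31 for portability
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 panel: TagPrimerPanel | None = None) -> PipelineResult:
    """Run every stage on one seed; returns the evaluation summary.

    Stage counts are logged as they accumulate; artifacts are written when
    ``out_dir`` is given.  Any stage failure raises (the CLI converts that
    into a nonzero exit).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    s_panel, s_sel, s_reads, s_cdna, s_creads = _child_seeds(cfg.seed, 5)

    if panel is None:
        panel = table1_panel(cfg.design.n_lines, cfg.design.individuals_per_line)

    # --- genomic side -----------------------------------------------------
    design = PanelDesign(**{**asdict(cfg.design), "seed": s_panel})
    genomes = simulate_panel(design, panel)
    logger.info("panel: %d individuals, %d planted variants",
                len(genomes.individuals), len(genomes.variants))
    amplicons = []
    for entry in panel.entries:
        amplicons.extend(make_aflp_amplicons(genomes, entry, cfg.enzymes))
    retained = size_select(amplicons, cfg.size_selection, s_sel)
    logger.info("amplicons: %d built, %d retained by size selection",
                len(amplicons), len(retained))
    if not retained:
        raise RuntimeError("size selection retained no amplicons")

    model = ReadModel(**{**asdict(cfg.read_model), "seed": s_reads})
    reads = simulate_reads(retained, model, cfg.n_reads_aflp, read_prefix="aflp")
    truth = {r.read_id: r.truth for r in reads}

    dmx = demux.demux_run(((r.read_id, r.sequence) for r in reads), panel,
                          cfg.demux_min_len, cfg.demux_max_mm,
                          out_dir=out / "demux" if out else None,
                          include_single_tag=cfg.include_single_tag)
    assert sum(dmx.counts.values()) == len(reads)
    logger.info("demux: %s", dmx.counts)
    rep = report.tag_report(dmx)
    headline = report.headline_stats(rep)

    # --- clustering + SNP candidates -------------------------------------
    seq_of = {r.read_id: r.sequence for r in reads}
    clustered_input = []
    for c in dmx.classifications:
        if c.category == "double_same":
            a, b = c.trimmed_interval
            clustered_input.append((c.read_id, seq_of[c.read_id][a:b]))
    clusters, singlets = cluster_snp.cluster_reads(
        clustered_input, cfg.min_identity, cfg.min_overlap)
    summary_depth = cluster_snp.depth_summary(clusters, singlets)
    ind_of = {}
    line_of_ind = {e.individual_id: e.line_id for e in panel.entries}
    for c in dmx.classifications:
        if c.category == "double_same":
            ind_of[c.read_id] = panel.individual_of(c.hits[0].tag)
    candidates = []
    for cl in clusters:
        candidates.extend(cluster_snp.call_snps(cl, ind_of, line_of_ind,
                                                cfg.min_allele_reads))
    recovery = evaluate.snp_recovery(candidates, clusters, genomes, truth,
                                     {rid for rid, _ in clustered_input},
                                     cfg.min_allele_reads)
    ok, total = evaluate.demux_accuracy(dmx.classifications, truth, panel)

    # --- cDNA side --------------------------------------------------------
    transcripts = simulate_transcripts(cfg.n_transcripts, cfg.cdna_mean_len,
                                       cfg.cdna_polya_mean, s_cdna)
    library = make_cdna_library(transcripts, cfg.uncut_prob, s_cdna + 1)
    cdna_reads = simulate_reads(library, model, cfg.n_reads_cdna,
                                seed=s_creads, read_prefix="cdna")
    cdna_pairs = [(r.read_id, r.sequence) for r in cdna_reads]
    qc = polya_qc.polya_qc_report(cdna_pairs, (out / "polya_qc.tsv") if out
                                  else Path("/dev/null"))

    summary = {
        "n_variants_planted": len(genomes.variants),
        "n_amplicons": len(amplicons),
        "n_amplicons_retained": len(retained),
        "n_reads_aflp": len(reads),
        "demux_counts": dict(dmx.counts),
        "headline": headline,
        "per_tag_occurrences": dict(rep.occurrences),
        "demux_accuracy": ok / total if total else None,
        "n_contigs": summary_depth.n_contigs,
        "n_singlets": summary_depth.n_singlets,
        "mean_depth": summary_depth.mean_depth,
        "n_snp_candidates": recovery.n_candidates,
        "n_recoverable": recovery.n_recoverable,
        "n_recovered": recovery.n_recovered,
        "snp_recovery_rate": recovery.recovery_rate,
        "n_line_specific": recovery.n_line_specific_candidates,
        "n_line_specific_false": recovery.n_line_specific_false,
        "n_reads_cdna": len(cdna_reads),
        "cdna_oligodt_hits": qc["oligodt_hits"],
        "cdna_oligodt_fraction": qc["oligodt_fraction"],
        "cdna_truth_uncut_fraction":
            sum(a.fragment_id.endswith(":uncut") for a in library) / len(library)
            if library else None,
    }

    if out is not None:
        io.write_fasta(((f"{ind}_h{h}", seq)
                        for ind, haps in genomes.individuals.items()
                        for h, seq in enumerate(haps)), out / "genomes.fasta")
        with open(out / "variants_truth.tsv", "w") as fh:
            fh.write("position\tref\talt\tline_specific\tline_id\tcarriers\n")
            for v in genomes.variants:
                carriers = ",".join(f"{i}:h{h}" for i, h in sorted(v.carriers))
                fh.write(f"{v.position}\t{v.ref}\t{v.alt}\t{int(v.line_specific)}"
                         f"\t{v.line_id or '.'}\t{carriers}\n")
        io.write_fasta(((a.fragment_id, a.sequence) for a in retained),
                       out / "amplicons.fasta")
        io.write_fastq(((r.read_id, r.sequence) for r in reads),
                       out / "reads_aflp.fastq")
        io.write_truth(reads, out / "truth_aflp.tsv")
        io.write_fastq(cdna_pairs, out / "reads_cdna.fastq")
        io.write_truth(cdna_reads, out / "truth_cdna.tsv")
        report.write_tag_report(rep, out / "tag_report.tsv")
        cluster_snp.write_consensus_fasta(clusters, out / "contigs.fasta")
        cluster_snp.write_snp_vcf(candidates, clusters, out / "snp_candidates.vcf")
        cluster_snp.write_snp_tsv(candidates, out / "snp_candidates.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineResult(cfg, summary, out)
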