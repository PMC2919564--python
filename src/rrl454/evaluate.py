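"""Truth-table evaluation of pipeline outputs.

The simulator tags every read with its source individual, fragment and the
planted-variant sites it covers (with the allele it carries).  These
helpers score the analysis stages against that truth: per-tag assignment
accuracy of the demultiplexer, and recovery of planted SNPs by the
clustering + candidate-calling stage.

Candidate-to-truth matching is done by flanking context: reads are ungapped
copies of genomic intervals, so a recovered variant's cluster-consensus
neighbourhood must match the ancestral neighbourhood of the planted site
(either orientation) around a center column carrying the right allele pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cluster_snp import ReadCluster, SnpCandidate
from .demux import ReadClassification
from .panel import TagPrimerPanel
from .protocol_sim import PanelGenomes, ReadTruth

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def demux_accuracy(classifications: Sequence[ReadClassification],
                   truth: Mapping[str, ReadTruth],
                   panel: TagPrimerPanel) -> tuple[int, int]:
    """(correctly assigned, total) over double-same-tag reads.

    A read is correctly assigned when its tag maps to the individual the
    truth table says it came from (chimeras judged by their 5' part).
    """
    ok = total = 0
    for c in classifications:
        if c.category != "double_same":
            continue
        total += 1
        if panel.individual_of(c.hits[0].tag) == truth[c.read_id].individual_id:
            ok += 1
    return ok, total


@dataclass(frozen=True)
class RecoveryResult:
    n_recoverable: int
    n_recovered: int
    n_candidates: int
    n_line_specific_candidates: int
    n_line_specific_false: int       # flags contradicted by the truth table

    @property
    def recovery_rate(self) -> float:
        if self.n_recoverable == 0:
            return float("nan")
        return self.n_recovered / self.n_recoverable


def _context_matches(consensus: str, offset: int, ancestor: str, pos: int,
                     window: int = 15, min_identity: float = 0.8) -> str | None:
    """Orientation ("+"/"-") under which the candidate context matches the
    ancestral context, or None.  The center column itself is excluded."""
    for orient in ("+", "-"):
        matches = compared = 0
        for d in range(-window, window + 1):
            if d == 0:
                continue
            ci = offset + d
            ai = pos + d if orient == "+" else pos - d
            if not (0 <= ci < len(consensus) and 0 <= ai < len(ancestor)):
                continue
            a = ancestor[ai] if orient == "+" else _COMP.get(ancestor[ai], "N")
            compared += 1
            if consensus[ci] == a:
                matches += 1
        if compared >= window and matches / compared >= min_identity:
            return orient
    return None


def snp_recovery(candidates: Sequence[SnpCandidate],
                 clusters: Sequence[ReadCluster],
                 genomes: PanelGenomes,
                 truth: Mapping[str, ReadTruth],
                 clustered_read_ids: set[str],
                 min_allele_reads: int = 2) -> RecoveryResult:
    """Score planted-SNP recovery.

    A planted variant is *recoverable* when, among the non-chimeric reads
    that entered clustering, each allele covers the site in at least
    ``min_allele_reads`` reads.  It is *recovered* when some candidate has
    the same allele pair (orientation-aware) and a matching flanking
    context.

    A line-specific flag counts as a *false positive* when it contradicts
    the truth table for the reads the caller actually used: the candidate
    matches no planted variant, or the alt-supporting member reads do not
    truly come from exactly one line, or the tag-derived line the flag
    names differs from that true line.  (A flag on a truth-shared variant
    whose alt reads genuinely all came from one line, or with ref/alt
    polarity flipped by the consensus majority, reflects what the sampled
    reads show — a sampling limitation, not an attribution error — and is
    not counted.)
    """
    cluster_of = {c.cluster_id: c for c in clusters}

    # allele-coverage census per planted site among clustered reads
    cov: dict[str, dict[str, int]] = {}
    for rid in clustered_read_ids:
        t = truth.get(rid)
        if t is None or t.is_chimera:
            continue
        for vstr in t.variants:
            key, allele = vstr.rsplit(":", 1)
            cov.setdefault(key, {"ref": 0, "alt": 0})[allele] += 1

    variants_by_key = {f"{v.position}:{v.ref}>{v.alt}": v for v in genomes.variants}
    recoverable = [variants_by_key[k] for k, c in cov.items()
                   if c["ref"] >= min_allele_reads and c["alt"] >= min_allele_reads]

    # match every candidate once, truth-variant side keyed for recovery
    matched_truth: dict[int, "object"] = {}
    for i, s in enumerate(candidates):
        cons = cluster_of[s.cluster_id].consensus
        best = None
        for v in genomes.variants:
            pair_fwd = {v.ref, v.alt}
            pair_rev = {_COMP[v.ref], _COMP[v.alt]}
            cand_pair = {s.ref_allele, s.alt_allele}
            if cand_pair != pair_fwd and cand_pair != pair_rev:
                continue
            orient = _context_matches(cons, s.offset, genomes.ancestor, v.position)
            if orient is None:
                continue
            expect = pair_fwd if orient == "+" else pair_rev
            if cand_pair == expect:
                best = v
                break
        if best is not None:
            matched_truth[i] = best

    recovered_positions = {v.position for v in matched_truth.values()}
    n_recovered = sum(1 for v in recoverable if v.position in recovered_positions)

    n_ls = sum(1 for s in candidates if s.line_specific)
    n_ls_false = 0
    for i, s in enumerate(candidates):
        if not s.line_specific:
            continue
        v = matched_truth.get(i)
        if v is None:
            n_ls_false += 1
            continue
        true_lines = {truth[r].line_id for r in s.alt_reads if r in truth}
        flag_lines = {genomes.lines[ind] for ind, (_r, a) in s.allele_depths.items()
                      if a > 0 and ind in genomes.lines}
        if len(true_lines) != 1 or flag_lines != true_lines:
            n_ls_false += 1
    return RecoveryResult(len(recoverable), n_recovered, len(candidates),
                          n_ls, n_ls_false)


def chimera_fraction(truth: Mapping[str, ReadTruth]) -> float:
    if not truth:
        return float("nan")
    return sum(t.is_chimera for t in truth.values()) / len(truth)
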