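"""Greedy clustering of trimmed reduced-representation reads and tag-aware
SNP-candidate detection.

Reads (tag/primer-trimmed) are clustered by greedy star clustering: reads
are sorted by (length desc, sequence asc) and each read joins the first
existing seed whose best ungapped-offset identity reaches ``min_identity``
over at least ``min_overlap`` bases (both strands tested); otherwise it
founds a new seed.  Clustering is ungapped by default — 454 indel errors
concentrate in homopolymers — which keeps the procedure simple and exactly
checkable against an exhaustive all-pairs oracle.

Within a cluster of depth >= 2*min_allele_reads, a consensus column is a
SNP candidate iff exactly two alleles are each supported by at least
``min_allele_reads`` reads and the column is covered by reads of at least
two distinct individuals.  Per-individual allele depths come from the demux
tag of each member read; a candidate is flagged line-specific when its
alternate allele is confined to the individuals of exactly one selection
line.  The thresholds are this package's declared procedure, not a
published standard.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_seq import reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Member:
    read_id: str
    offset: int          # start of the oriented read on the cluster axis
    strand: str          # "+" or "-"
    oriented_seq: str    # the read as aligned (revcomped for "-")


@dataclass
class ReadCluster:
    cluster_id: int
    members: list[Member]
    consensus: str = ""

    @property
    def depth(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SnpCandidate:
    cluster_id: int
    offset: int                       # 0-based on the cluster consensus
    ref_allele: str
    alt_allele: str
    # individual -> (ref depth, alt depth)
    allele_depths: Mapping[str, tuple[int, int]]
    line_specific: bool
    flank: int                        # distance to the nearer consensus edge
    alt_reads: tuple[str, ...] = ()   # member reads supporting the alt allele

    @property
    def depth(self) -> int:
        return sum(r + a for r, a in self.allele_depths.values())


# ---------------------------------------------------------------------------
# pairwise ungapped identity

def best_offset_identity(a: str, b: str, min_overlap: int,
                         offsets: Iterable[int] | None = None,
                         ) -> tuple[float, int] | None:
    """Best ungapped identity of ``b`` laid against ``a`` over all offsets.

    Offset o places b[i] against a[o + i].  Returns (identity, offset) for
    the maximal identity among placements with overlap >= min_overlap
    (smallest such offset on ties), or None if no placement has enough
    overlap.  ``offsets`` restricts the search (k-mer candidates); None
    scans exhaustively.
    """
    la, lb = len(a), len(b)
    if offsets is None:
        offsets = range(-(lb - min_overlap), la - min_overlap + 1)
    best: tuple[float, int] | None = None
    for o in offsets:
        start_b = max(0, -o)
        end_b = min(lb, la - o)
        ov = end_b - start_b
        if ov < min_overlap:
            continue
        matches = sum(b[i] == a[o + i] for i in range(start_b, end_b))
        ident = matches / ov
        if best is None or ident > best[0] or (ident == best[0] and o < best[1]):
            best = (ident, o)
    return best


class _KmerIndex:
    """k-mer -> (seed_id, position) postings over all seed sequences."""

    def __init__(self, k: int) -> None:
        self.k = k
        self.post: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def add(self, seed_id: int, seq: str) -> None:
        k = self.k
        for i in range(len(seq) - k + 1):
            self.post[seq[i:i + k]].append((seed_id, i))

    def candidate_offsets(self, seq: str, stride: int = 4) -> dict[int, set[int]]:
        """seed_id -> candidate offsets implied by shared k-mers."""
        k = self.k
        cand: dict[int, set[int]] = defaultdict(set)
        positions = list(range(0, max(1, len(seq) - k + 1), stride))
        if positions and positions[-1] != len(seq) - k and len(seq) >= k:
            positions.append(len(seq) - k)
        for i in positions:
            for seed_id, j in self.post.get(seq[i:i + k], ()):
                cand[seed_id].add(j - i)
        return cand


def cluster_reads(reads: Sequence[tuple[str, str]], min_identity: float = 0.95,
                  min_overlap: int = 50, k: int = 12,
                  ) -> tuple[list[ReadCluster], list[str]]:
    """Greedy star clustering; returns (contigs, singlet read ids).

    Deterministic for a fixed read multiset: input is first sorted by
    (length desc, sequence asc, read id asc).  Candidate seed placements are
    found through a k-mer index and verified by exact ungapped identity; at
    the identity levels the pipeline operates at, the shared-k-mer anchor
    recovers every qualifying placement (the test suite checks exact
    membership agreement with an exhaustive all-offsets oracle).

    Clusters with a single member are reported as singlets, the rest as
    contigs with a majority-vote consensus.
    """
    ordered = sorted(reads, key=lambda r: (-len(r[1]), r[1], r[0]))
    index = _KmerIndex(k)
    clusters: list[ReadCluster] = []
    for read_id, seq in ordered:
        placed = False
        strands = ((seq, "+"), (reverse_complement(seq), "-"))
        # collect, per seed, the best qualifying placement on either strand
        per_seed: dict[int, tuple[float, int, str, str]] = {}
        for oriented, strand in strands:
            if len(oriented) < k:
                continue
            for seed_id, offs in index.candidate_offsets(oriented).items():
                seed_seq = clusters[seed_id].members[0].oriented_seq
                hit = best_offset_identity(seed_seq, oriented, min_overlap, sorted(offs))
                if hit is None or hit[0] < min_identity:
                    continue
                cur = per_seed.get(seed_id)
                if cur is None or hit[0] > cur[0]:
                    per_seed[seed_id] = (hit[0], hit[1], strand, oriented)
        if per_seed:
            seed_id = min(per_seed)          # first seed in creation order
            _ident, off, strand, oriented = per_seed[seed_id]
            clusters[seed_id].members.append(Member(read_id, off, strand, oriented))
            placed = True
        if not placed:
            cid = len(clusters)
            clusters.append(ReadCluster(cid, [Member(read_id, 0, "+", seq)]))
            index.add(cid, seq)
    contigs: list[ReadCluster] = []
    singlets: list[str] = []
    for c in clusters:
        if c.depth == 1:
            singlets.append(c.members[0].read_id)
        else:
            _finalize(c)
            contigs.append(c)
    # renumber contigs densely
    for i, c in enumerate(contigs):
        c.cluster_id = i
    return contigs, singlets


def _finalize(cluster: ReadCluster) -> None:
    """Rebase member offsets to 0 and compute the majority consensus."""
    shift = -min(m.offset for m in cluster.members)
    cluster.members = [Member(m.read_id, m.offset + shift, m.strand, m.oriented_seq)
                       for m in cluster.members]
    length = max(m.offset + len(m.oriented_seq) for m in cluster.members)
    cons = []
    for col in range(length):
        votes = Counter()
        for m in cluster.members:
            i = col - m.offset
            if 0 <= i < len(m.oriented_seq):
                votes[m.oriented_seq[i]] += 1
        if not votes:
            cons.append("N")
            continue
        top = max(votes.values())
        cons.append(min(b for b, n in votes.items() if n == top))
    cluster.consensus = "".join(cons)


# ---------------------------------------------------------------------------
# SNP candidates

def call_snps(cluster: ReadCluster,
              individual_of: Mapping[str, str], line_of: Mapping[str, str],
              min_allele_reads: int = 2) -> list[SnpCandidate]:
    """Per-column biallelic SNP candidates on a cluster.

    ``individual_of`` / ``line_of`` map read ids to their demux-derived
    individual and line.  Columns with three or more alleles above the
    support threshold are skipped (logged): at desk error rates they are
    alignment artefacts, not credible tri-allelic sites.
    """
    if cluster.depth < 2 * min_allele_reads:
        return []
    out: list[SnpCandidate] = []
    for col in range(len(cluster.consensus)):
        by_allele: dict[str, list[str]] = defaultdict(list)
        for m in cluster.members:
            i = col - m.offset
            if 0 <= i < len(m.oriented_seq):
                by_allele[m.oriented_seq[i]].append(m.read_id)
        supported = {b: rids for b, rids in by_allele.items()
                     if len(rids) >= min_allele_reads}
        if len(supported) < 2:
            continue
        if len(supported) > 2:
            logger.info("cluster %d col %d: %d alleles above threshold, skipped",
                        cluster.cluster_id, col, len(supported))
            continue
        inds_at_col = {individual_of[r] for rids in supported.values() for r in rids
                       if r in individual_of}
        if len(inds_at_col) < 2:
            continue
        cons_base = cluster.consensus[col]
        alleles = sorted(supported, key=lambda b: (-len(supported[b]), b))
        if cons_base in supported:
            ref = cons_base
            alt = next(b for b in alleles if b != ref)
        else:
            ref, alt = alleles[0], alleles[1]
        depths: dict[str, list[int]] = defaultdict(lambda: [0, 0])
        for which, base in ((0, ref), (1, alt)):
            for rid in supported[base]:
                ind = individual_of.get(rid)
                if ind is not None:
                    depths[ind][which] += 1
        alt_lines = {line_of[ind] for ind, (r, a) in depths.items()
                     if a > 0 and ind in line_of}
        line_specific = len(alt_lines) == 1
        out.append(SnpCandidate(
            cluster.cluster_id, col, ref, alt,
            {ind: (r, a) for ind, (r, a) in depths.items()},
            line_specific,
            min(col, len(cluster.consensus) - 1 - col),
            tuple(sorted(supported[alt]))))
    return out


# ---------------------------------------------------------------------------
# summaries and writers

@dataclass(frozen=True)
class DepthSummary:
    n_contigs: int
    n_singlets: int
    mean_depth: float
    min_depth: int
    max_depth: int


def depth_summary(clusters: Sequence[ReadCluster],
                  singlets: Sequence[str]) -> DepthSummary:
    """Contig/singlet census in the style of an assembly report."""
    if not clusters:
        return DepthSummary(0, len(singlets), 0.0, 0, 0)
    depths = [c.depth for c in clusters]
    return DepthSummary(len(clusters), len(singlets),
                        sum(depths) / len(depths), min(depths), max(depths))


def write_consensus_fasta(clusters: Sequence[ReadCluster], path: str | Path) -> None:
    from .io import write_fasta
    write_fasta(((f"cluster_{c.cluster_id}", c.consensus) for c in clusters), path)


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rrl454
##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting read depth (both alleles)">
##INFO=<ID=AD,Number=.,Type=String,Description="Per-individual depths as individual|ref|alt">
##INFO=<ID=LINE_SPECIFIC,Number=0,Type=Flag,Description="Alternate allele confined to one selection line">
"""


def write_snp_vcf(candidates: Sequence[SnpCandidate],
                  clusters: Sequence[ReadCluster], path: str | Path) -> None:
    """Minimal sites-only VCF against the cluster consensi (POS is 1-based)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in clusters:
            fh.write(f"##contig=<ID=cluster_{c.cluster_id},length={len(c.consensus)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(candidates, key=lambda s: (s.cluster_id, s.offset)):
            ad = ",".join(f"{ind}|{r}|{a}" for ind, (r, a)
                          in sorted(s.allele_depths.items()))
            info = f"DP={s.depth};AD={ad}"
            if s.line_specific:
                info += ";LINE_SPECIFIC"
            fh.write(f"cluster_{s.cluster_id}\t{s.offset + 1}\t.\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t.\tPASS\t{info}\n")


def write_snp_tsv(candidates: Sequence[SnpCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\toffset\tref\talt\tdepth\tline_specific\tallele_depths\tflank\n")
        for s in sorted(candidates, key=lambda s: (s.cluster_id, s.offset)):
            ad = ",".join(f"{ind}:{r}:{a}" for ind, (r, a)
                          in sorted(s.allele_depths.items()))
            fh.write(f"{s.cluster_id}\t{s.offset}\t{s.ref_allele}\t{s.alt_allele}\t"
                     f"{s.depth}\t{int(s.line_specific)}\t{ad}\t{s.flank}\n")
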