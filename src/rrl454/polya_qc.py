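"""cDNA-side quality analysis.

Two checks on a GsuI-trimmed, non-amplified cDNA library: how many reads
still display the modified oligo(dT) primer (GAGAGAGAGACTGGAG(T)16VN — the
residue of a failed GsuI digestion), and the homopolymer-run profile that
the trim is meant to tame (long T tracts degrade 454 base calling).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .core_seq import IUPAC_SETS, reverse_complement

OLIGODT_HEAD = "GAGAGAGAGACTGGAG"


@dataclass(frozen=True)
class OligoDtPattern:
    """The modified oligo(dT) primer: head + T tract + anchoring VN."""

    head: str = OLIGODT_HEAD
    t_run: int = 16
    tail: str = "VN"

    @property
    def full(self) -> str:
        return self.head + "T" * self.t_run + self.tail

    def __post_init__(self) -> None:
        if len(self.full) != len(self.head) + self.t_run + len(self.tail):
            raise ValueError("inconsistent pattern")


def _mm_at(seq: str, pattern: str, pos: int, budget: int) -> int | None:
    """IUPAC-aware mismatch count of pattern at pos, or None past budget."""
    if pos + len(pattern) > len(seq):
        return None
    mm = 0
    for p, s in zip(pattern, seq[pos:pos + len(pattern)]):
        if s not in IUPAC_SETS[p]:
            mm += 1
            if mm > budget:
                return None
    return mm


def find_oligodt(read_seq: str, pattern: OligoDtPattern | None = None,
                 max_mm: int = 3, t_run_slop: int = 2) -> int | None:
    """First position (either strand) of the oligo(dT) primer pattern.

    Matching allows up to ``max_mm`` substitutions over the pattern, the VN
    anchor matched under IUPAC semantics, and the T tract to vary by
    ``t_run_slop`` nt around its nominal 16 (454 homopolymer indels).
    Returns the 0-based start on the read's forward strand coordinate
    system, or None.
    """
    if pattern is None:
        pattern = OligoDtPattern()
    variants = [pattern.head + "T" * t + pattern.tail
                for t in range(max(1, pattern.t_run - t_run_slop),
                               pattern.t_run + t_run_slop + 1)]
    fwd = read_seq.upper()
    for strand_seq in (fwd, reverse_complement(fwd)):
        for pos in range(len(strand_seq)):
            for pat in variants:
                if _mm_at(strand_seq, pat, pos, max_mm) is not None:
                    return pos
    return None


@dataclass
class HomopolymerProfile:
    """Maximal-run histogram: (base, run_length) -> count, plus summaries."""

    histogram: Counter
    n_reads: int
    total_bases: int
    longest_run: int
    frac_reads_with_run_ge: dict[int, float]


def _max_runs(seq: str) -> Iterable[tuple[str, int]]:
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        yield seq[i], j - i
        i = j


def homopolymer_profile(reads: Iterable[tuple[str, str]],
                        thresholds: tuple[int, ...] = (8, 12, 16),
                        ) -> HomopolymerProfile:
    """Profile maximal homopolymer runs over a read set.

    Counts every maximal run per base, the longest run seen, and the
    fraction of reads containing any run >= k for each threshold.
    """
    hist: Counter = Counter()
    n_reads = 0
    total = 0
    longest = 0
    ge_counts = {k: 0 for k in thresholds}
    for _rid, seq in reads:
        n_reads += 1
        total += len(seq)
        read_longest = 0
        for base, run in _max_runs(seq.upper()):
            hist[(base, run)] += 1
            read_longest = max(read_longest, run)
        longest = max(longest, read_longest)
        for k in thresholds:
            if read_longest >= k:
                ge_counts[k] += 1
    frac = {k: (ge_counts[k] / n_reads if n_reads else 0.0) for k in thresholds}
    return HomopolymerProfile(hist, n_reads, total, longest, frac)


def polya_qc_report(reads: list[tuple[str, str]], out_path: str | Path,
                    max_mm: int = 3) -> dict:
    """Scan a library and write the TSV report; returns the summary dict."""
    hits = sum(1 for _rid, seq in reads if find_oligodt(seq, max_mm=max_mm) is not None)
    prof = homopolymer_profile(reads)
    summary = {
        "reads_scanned": len(reads),
        "oligodt_hits": hits,
        "oligodt_fraction": hits / len(reads) if reads else 0.0,
        "longest_run": prof.longest_run,
        **{f"frac_run_ge_{k}": v for k, v in prof.frac_reads_with_run_ge.items()},
    }
    with open(out_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
        fh.write("base\trun_length\tcount\n")
        for (base, run), count in sorted(prof.histogram.items()):
            fh.write(f"{base}\t{run}\t{count}\n")
    return summary
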