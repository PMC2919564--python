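"""Dual-end tag demultiplexing of tagged-AFLP 454 reads.

Reads longer than the analysis cutoff (120 bp) are scanned at both ends for
a tagged AFLP primer: a 4-nt tag followed by the constant Eco or Taq primer
core.  The tag is matched literally (sequencing errors there produce "false
tags" — 4-mers absent from the designed set) while the primer core tolerates
a configurable number of substitutions.  Categories partition every input
read:

- ``too_short``    length <= min_len, excluded from tag statistics
- ``untagged``     no primer at either end
- ``single_tag``   a valid tagged primer at one end only
- ``double_same``  valid identical tags at both ends -> attributable reads
- ``double_diff``  two valid but different tags -> chimera signature
- ``false_tag``    a primer hit whose adjacent 4-mer is not a panel tag

The default scan is an ungapped Hamming comparison at offset 0 (454 indel
errors concentrate in homopolymers, which the primers avoid); an optional
edit-distance mode (edlib) is available for real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .core_seq import hamming, reverse_complement
from .panel import TagPrimerPanel

logger = logging.getLogger(__name__)

CATEGORIES = ("too_short", "untagged", "single_tag", "double_same",
              "double_diff", "false_tag")

TAG_LEN = 4


@dataclass(frozen=True)
class EndHit:
    end: Literal["five_prime", "three_prime"]
    tag: str
    primer_family: Literal["Eco", "Taq"]
    mismatches: int
    valid_tag: bool
    span: int          # tag + core length consumed at this end


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    category: str
    hits: tuple[EndHit, ...]
    trimmed_interval: tuple[int, int]

    @property
    def tag(self) -> str | None:
        """The individual tag, defined for double_same reads."""
        if self.category == "double_same":
            return self.hits[0].tag
        return None


def _cores(panel: TagPrimerPanel) -> dict[str, str]:
    e = panel.entries[0]
    return {"Eco": e.eco_primer[TAG_LEN:], "Taq": e.taq_primer[TAG_LEN:]}


def scan_end(read_seq: str, panel: TagPrimerPanel, max_primer_mm: int = 2,
             end: Literal["five_prime", "three_prime"] = "five_prime",
             mode: Literal["hamming", "edit"] = "hamming") -> EndHit | None:
    """Detect a tagged primer at one read end.

    The 5' test takes read positions [0, 4) as the tag and compares the
    following bases to each family core (Hamming, offset 0); the 3' test is
    the same scan on the reverse complement.  The family with the better
    core score wins; ties go to Eco (logged).  A core match whose 4-mer is
    not a panel tag is returned with ``valid_tag=False``.
    """
    seq = read_seq if end == "five_prime" else reverse_complement(read_seq)
    cores = _cores(panel)
    if mode == "edit":
        return _scan_end_edit(seq, panel, cores, max_primer_mm, end)
    best: tuple[int, str] | None = None
    tie = False
    for family in ("Eco", "Taq"):   # Eco first -> ties resolve to Eco
        core = cores[family]
        if len(seq) < TAG_LEN + len(core):
            continue
        mm = hamming(seq[TAG_LEN:TAG_LEN + len(core)], core)
        if mm > max_primer_mm:
            continue
        if best is None or mm < best[0]:
            best = (mm, family)
        elif mm == best[0]:
            tie = True
    if best is None:
        return None
    if tie:
        logger.info("core-score tie at %s end; resolved to Eco", end)
    mm, family = best
    tag = seq[:TAG_LEN]
    return EndHit(end, tag, family, mm, tag in panel.tags,
                  TAG_LEN + len(cores[family]))


def _scan_end_edit(seq: str, panel: TagPrimerPanel, cores: dict[str, str],
                   max_mm: int, end: str) -> EndHit | None:
    """Edit-distance fallback for real reads with indels near the primer."""
    import edlib
    best = None
    window = seq[:TAG_LEN + max(len(c) for c in cores.values()) + 4]
    for family in ("Eco", "Taq"):
        res = edlib.align(cores[family], window, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_mm:
            continue
        start = res["locations"][0][0]
        if start < TAG_LEN:
            continue
        cand = (res["editDistance"], family, start)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        return None
    mm, family, start = best
    tag = seq[start - TAG_LEN:start]
    return EndHit(end, tag, family, mm, tag in panel.tags,  # type: ignore[arg-type]
                  start + len(cores[family]))


def classify_read(read_id: str, seq: str, panel: TagPrimerPanel,
                  min_len: int = 120, max_primer_mm: int = 2,
                  mode: Literal["hamming", "edit"] = "hamming",
                  ) -> ReadClassification:
    """Assign a read to exactly one tag-analysis category.

    Only reads strictly longer than ``min_len`` are analysed for tags.  Any
    primer hit with a non-panel 4-mer makes the read ``false_tag``
    (separated from ``double_diff``, which is reserved for two valid tags).
    The trimmed interval excludes the detected tag+core spans.
    """
    n = len(seq)
    if n <= min_len:
        return ReadClassification(read_id, "too_short", (), (0, n))
    hit5 = scan_end(seq, panel, max_primer_mm, "five_prime", mode)
    hit3 = scan_end(seq, panel, max_primer_mm, "three_prime", mode)
    hits = tuple(h for h in (hit5, hit3) if h is not None)
    start = hit5.span if hit5 else 0
    end = n - hit3.span if hit3 else n
    interval = (min(start, end), end) if end >= start else (start, start)
    if not hits:
        return ReadClassification(read_id, "untagged", (), (0, n))
    if any(not h.valid_tag for h in hits):
        return ReadClassification(read_id, "false_tag", hits, interval)
    if len(hits) == 1:
        return ReadClassification(read_id, "single_tag", hits, interval)
    if hits[0].tag == hits[1].tag:
        return ReadClassification(read_id, "double_same", hits, interval)
    return ReadClassification(read_id, "double_diff", hits, interval)


@dataclass
class DemuxResult:
    classifications: list[ReadClassification]
    counts: dict[str, int]
    per_tag: dict[str, int]        # double_same occurrences per tag


CLASSIFICATION_COLUMNS = ("read_id", "category", "tag5", "tag3", "family5",
                          "family3", "mm5", "mm3", "trim_start", "trim_end")


def demux_run(reads: Iterable[tuple[str, str]], panel: TagPrimerPanel,
              min_len: int = 120, max_primer_mm: int = 2,
              mode: Literal["hamming", "edit"] = "hamming",
              out_dir: str | Path | None = None,
              include_single_tag: bool = False) -> DemuxResult:
    """Classify every read; optionally write the TSV and per-tag FASTQ files.

    Every input read lands in exactly one category.  Per-tag FASTQ files
    receive the trimmed ``double_same`` (and, opted in, ``single_tag``)
    reads; they are what downstream clustering consumes.
    """
    counts = {c: 0 for c in CATEGORIES}
    per_tag: dict[str, int] = {e.tag: 0 for e in panel.entries}
    classifications: list[ReadClassification] = []
    tag_reads: dict[str, list[tuple[str, str]]] = {e.tag: [] for e in panel.entries}
    for read_id, seq in reads:
        c = classify_read(read_id, seq, panel, min_len, max_primer_mm, mode)
        classifications.append(c)
        counts[c.category] += 1
        keep_tag = None
        if c.category == "double_same":
            keep_tag = c.hits[0].tag
            per_tag[keep_tag] += 1
        elif include_single_tag and c.category == "single_tag" and c.hits[0].valid_tag:
            keep_tag = c.hits[0].tag
        if keep_tag is not None:
            a, b = c.trimmed_interval
            tag_reads[keep_tag].append((read_id, seq[a:b]))
    if out_dir is not None:
        from .io import write_fastq
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_classification_tsv(classifications, out / "classification.tsv")
        for tag, rs in tag_reads.items():
            if rs:
                write_fastq(rs, out / f"{tag}.fastq")
    return DemuxResult(classifications, counts, per_tag)


def write_classification_tsv(classifications: Iterable[ReadClassification],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFICATION_COLUMNS) + "\n")
        for c in classifications:
            by_end = {h.end: h for h in c.hits}
            h5, h3 = by_end.get("five_prime"), by_end.get("three_prime")
            fh.write("\t".join([
                c.read_id, c.category,
                h5.tag if h5 else ".", h3.tag if h3 else ".",
                h5.primer_family if h5 else ".", h3.primer_family if h3 else ".",
                str(h5.mismatches) if h5 else ".", str(h3.mismatches) if h3 else ".",
                str(c.trimmed_interval[0]), str(c.trimmed_interval[1]),
            ]) + "\n")
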