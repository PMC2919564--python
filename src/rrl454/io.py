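"""FASTA/FASTQ and truth-table IO, via Biopython.

Reads are written Phred+33 with a constant quality (default Q30): the read
simulator does not model per-base quality, and the classifiers ignore it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .protocol_sim import ReadTruth, SimulatedRead

TRUTH_COLUMNS = ("read_id", "individual_id", "line_id", "fragment_id",
                 "is_chimera", "variants")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    return SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality: int = 30) -> int:
    def recs():
        for name, seq in reads:
            r = SeqRecord(Seq(seq), id=name, description="")
            r.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield r
    return SeqIO.write(recs(), str(path), "fastq")


def read_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Read FASTQ or FASTA (sniffed from the first byte) as (id, seq) pairs."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for i, rec in enumerate(SeqIO.parse(path, fmt)):
        try:
            yield rec.id, str(rec.seq).upper()
        except Exception as exc:  # pragma: no cover - malformed record
            raise ValueError(f"unreadable {fmt} record {i + 1} in {path}") from exc


def write_truth(reads: Iterable[SimulatedRead | ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in reads:
            t = r.truth if isinstance(r, SimulatedRead) else r
            fh.write(f"{t.read_id}\t{t.individual_id}\t{t.line_id}\t"
                     f"{t.fragment_id}\t{int(t.is_chimera)}\t{','.join(t.variants)}\n")


def read_truth(path: str | Path) -> dict[str, ReadTruth]:
    out: dict[str, ReadTruth] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth-table header in {path}")
        for ln in fh:
            rid, ind, line, frag, chim, var = ln.rstrip("\n").split("\t")
            out[rid] = ReadTruth(rid, ind, line, frag, chim == "1",
                                 tuple(v for v in var.split(",") if v))
    return out
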