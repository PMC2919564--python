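"""Tagged-primer panel: 4-nt individual tags on AFLP preamplification primers.

Each individual of the multiplexed AFLP library is amplified with an Eco- and
a Taq-side primer carrying the *same* 4-nt 5' tag, so the tag read at either
end of a sequence identifies its animal of origin.  The default panel is the
eight published tag pairs; the study design assigns the first six tags to
3 selection lines x 2 individuals.

The 5'-phosphate modification on the physical primers (needed for sequencing-
adapter ligation) is chemistry only and is not part of the sequence text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

#: Constant primer cores downstream of the 4-nt tag.
ECO_CORE = "CTGCGTTACCAATTCA"
TAQ_CORE = "GATGAGTCCTGACCGAA"

#: The eight published tags, in table order.
TABLE1_TAGS = ("TACG", "TAGA", "TATC", "TCAG", "TCGT", "TCTA", "TGAT", "TGCA")


@dataclass(frozen=True)
class PanelEntry:
    tag: str
    eco_primer: str
    taq_primer: str
    individual_id: str
    line_id: str

    def __post_init__(self) -> None:
        if len(self.tag) != 4:
            raise ValueError(f"tag must be 4 nt, got {self.tag!r}")
        if not self.eco_primer.startswith(self.tag) or not self.taq_primer.startswith(self.tag):
            raise ValueError("full primer must be tag + constant core")


@dataclass(frozen=True)
class TagPrimerPanel:
    """Maps 4-nt tags to individuals and lines, with their full primers."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        tags = [e.tag for e in self.entries]
        if len(set(tags)) != len(tags):
            raise ValueError("panel tags must be unique")

    @property
    def tags(self) -> frozenset[str]:
        return frozenset(e.tag for e in self.entries)

    def by_tag(self, tag: str) -> PanelEntry:
        for e in self.entries:
            if e.tag == tag:
                return e
        raise KeyError(tag)

    def individual_of(self, tag: str) -> str:
        return self.by_tag(tag).individual_id

    def line_of(self, tag: str) -> str:
        return self.by_tag(tag).line_id

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(e.individual_id for e in self.entries)

    def to_tsv(self, path: str | Path) -> None:
        """Write as a (name, sequence) two-column table."""
        with open(path, "w") as fh:
            fh.write("name\tsequence\n")
            for e in self.entries:
                fh.write(f"EcoAp{e.tag}\t{e.eco_primer}\n")
                fh.write(f"TaqAp{e.tag}\t{e.taq_primer}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n_lines: int = 3,
                 individuals_per_line: int = 2) -> "TagPrimerPanel":
        """Read a (name, sequence) primer table.

        Primer names are expected as Eco/Taq + anything + 4-nt tag suffix
        (e.g. ``EcoApTACG``); a leading ``P-`` phosphate marker on the
        sequence is stripped.  Individuals/lines are assigned in tag order.
        """
        eco: dict[str, str] = {}
        taq: dict[str, str] = {}
        order: list[str] = []
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.lower().startswith("name\t"):
                    continue
                name, seq = ln.split("\t")[:2]
                seq = seq.removeprefix("P-").upper()
                tag = name[-4:].upper()
                if tag not in order:
                    order.append(tag)
                (eco if name.lower().startswith("eco") else taq)[tag] = seq
        entries = []
        for i, tag in enumerate(order):
            if tag not in eco or tag not in taq:
                raise ValueError(f"tag {tag} lacks an Eco or Taq primer")
            line = i // individuals_per_line + 1
            ind = i % individuals_per_line + 1
            if line <= n_lines:
                entries.append(PanelEntry(tag, eco[tag], taq[tag],
                                          f"L{line}-{ind}", f"L{line}"))
        return cls(tuple(entries))


def table1_panel(n_lines: int = 3, individuals_per_line: int = 2) -> TagPrimerPanel:
    """The default study panel: published tag pairs assigned to lines.

    The first ``n_lines * individuals_per_line`` tags are assigned to
    individuals ``L<line>-<k>`` in table order (default six of the eight
    published pairs, matching the 3-lines-x-2-individuals design).
    """
    n = n_lines * individuals_per_line
    if n > len(TABLE1_TAGS):
        raise ValueError(f"panel has only {len(TABLE1_TAGS)} tag pairs, {n} requested")
    entries = []
    for i in range(n):
        tag = TABLE1_TAGS[i]
        line = i // individuals_per_line + 1
        ind = i % individuals_per_line + 1
        entries.append(PanelEntry(tag, tag + ECO_CORE, tag + TAQ_CORE,
                                  f"L{line}-{ind}", f"L{line}"))
    return TagPrimerPanel(tuple(entries))
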