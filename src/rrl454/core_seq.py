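"""Nucleotide-sequence primitives.

IUPAC-aware matching, reverse complementation, and restriction digestion
with arbitrary cut offsets — including type IIS enzymes such as GsuI that
cleave well downstream of their recognition site.

Coordinates are 0-based, half-open throughout.  Digestion is reported on
the top strand only: the bottom-strand cut offset is carried on the enzyme
(it fixes the overhang geometry) but fragments are emitted as single
top-strand texts, since sequencing reads are single-stranded observables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to the set of bases each represents.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)

_IUPAC_RE_CLASS = {code: ("[" + "".join(sorted(bases)) + "]" if len(bases) > 1 else next(iter(bases)))
                   for code, bases in IUPAC_SETS.items()}


class SequenceError(ValueError):
    """Raised on sequences or patterns containing non-IUPAC characters."""


def _validate_iupac(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise SequenceError(f"non-IUPAC character(s) {sorted(bad)} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, with ambiguity codes mapped (V<->B, N<->N)."""
    _validate_iupac(seq)
    return seq.translate(_COMP_TABLE)[::-1]


def iupac_matches(seq: str, pattern: str, pos: int) -> bool:
    """True if ``pattern`` matches ``seq`` at ``pos`` under IUPAC semantics.

    Both operands may contain ambiguity codes; a position matches when the two
    base sets intersect.
    """
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for p, s in zip(pattern, seq[pos:pos + len(pattern)]):
        if not (IUPAC_SETS[p] & IUPAC_SETS[s]):
            return False
    return True


def iupac_find(seq: str, pattern: str) -> list[int]:
    """All 0-based start positions where ``pattern`` matches ``seq``.

    IUPAC ambiguity codes in the pattern match their base sets (V = A/C/G,
    N = any); overlapping occurrences are all reported, in ascending order.
    Only A/C/G/T in the subject are matched literally against pattern codes.
    """
    if not pattern:
        raise SequenceError("empty pattern")
    s = _validate_iupac(seq)
    p = _validate_iupac(pattern, "pattern")
    regex = "(?=" + "".join(_IUPAC_RE_CLASS[c] for c in p) + ")"
    return [m.start() for m in re.finditer(regex, s)]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings (IUPAC-blind, literal)."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with recognition site and strand cut offsets.

    ``cut_top`` / ``cut_bottom`` are offsets in nt from the 3' end of the
    recognition site on the respective strand; 0 cuts immediately after the
    site, negative values cut within or before it.  EcoRI (G^AATTC) is
    cut_top=-5; GsuI (CTGGAG 16/14) is cut_top=16, cut_bottom=14, leaving a
    2-nt 3' overhang.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        _validate_iupac(self.recognition, f"{self.name} recognition site")

    @property
    def overhang(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    def cut_positions(self, seq: str, mask: "MethylationMask | None" = None) -> list[int]:
        """Top-strand cut coordinates in ``seq``, skipping masked sites.

        Sites whose cut position falls outside the sequence (possible for
        downstream cutters near the 3' end) are skipped with a log message.
        """
        protected = mask.protected_positions if mask else frozenset()
        cuts = []
        for site in iupac_find(seq, self.recognition):
            if site in protected:
                continue
            pos = site + len(self.recognition) + self.cut_top
            if 0 < pos < len(seq):
                cuts.append(pos)
            else:
                logger.info("%s site at %d: cut position %d outside sequence, skipped",
                            self.name, site, pos)
        return cuts


# Default enzyme panel; offsets are configuration data, overridable from the
# pipeline config.
ECORI = RestrictionEnzyme("EcoRI", "GAATTC", cut_top=-5, cut_bottom=-1)
TAQI = RestrictionEnzyme("TaqI", "TCGA", cut_top=-3, cut_bottom=-1)
GSUI = RestrictionEnzyme("GsuI", "CTGGAG", cut_top=16, cut_bottom=14)

DEFAULT_ENZYMES = {"EcoRI": ECORI, "TaqI": TAQI, "GsuI": GSUI}


@dataclass(frozen=True)
class MethylationMask:
    """Positions of recognition sites exempt from cleavage.

    Positional masking models hemimethylation protection (methylated-dCTP
    first-strand synthesis shielding internal GsuI sites) without simulating
    methyl chemistry.
    """

    protected_positions: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def all_sites(cls, seq: str, enzyme: RestrictionEnzyme) -> "MethylationMask":
        return cls(frozenset(iupac_find(seq, enzyme.recognition)))


@dataclass
class Fragment:
    """A digestion product on the top strand.

    ``left_end`` / ``right_end`` name the enzyme that generated each end
    ("none" at the molecule termini).
    """

    sequence: str
    start: int
    end: int
    left_end: str
    right_end: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates do not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


def digest(seq: str, enzymes: list[RestrictionEnzyme],
           mask: MethylationMask | None = None,
           source_id: str = "") -> list[Fragment]:
    """Digest ``seq`` with all ``enzymes`` simultaneously.

    All unmasked sites of every enzyme are cut (ties between overlapping
    sites of different enzymes are not special-cased: each contributes its
    cut position).  Fragments tile the input exactly once on the top-strand
    convention — each spans [previous cut, next cut) — and are returned
    5'->3'.  End labels record the generating enzyme.
    """
    s = _validate_iupac(seq)
    cutlist: list[tuple[int, str]] = []
    for enz in enzymes:
        cutlist.extend((pos, enz.name) for pos in enz.cut_positions(s, mask))
    cutlist.sort()
    bounds = [(0, "none")] + cutlist + [(len(s), "none")]
    frags = []
    for (a, left_label), (b, right_label) in zip(bounds, bounds[1:]):
        if b == a:
            # two enzymes cutting at the same coordinate; zero-length piece dropped
            logger.info("coincident cuts at %d; empty fragment suppressed", a)
            continue
        frags.append(Fragment(s[a:b], a, b, left_label, right_label, source_id))
    return frags
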