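"""Synthetic-data generator emulating the two reduced-representation protocols.

Genomic side: an ancestral sequence is mutated into selection lines and then
individuals (SNPs only, so coordinates stay ancestral); each individual's
diploid genome is double-digested with EcoRI+TaqI and Eco-Taq fragments are
turned into tagged preamplification amplicons (tagged primer + insert +
reverse-complemented tagged primer, same 4-nt tag at both ends per
individual), then gel size selection keeps a 200-400 bp nominal window with
stochastic leakage over a wider 100-500 bp interval.

cDNA side: polyadenylated transcripts are reverse-transcribed with the
anchored oligo(dT) primer GAGAGAGAGACTGGAG(T)16VN carrying a GsuI site;
GsuI cleaves 16 nt downstream of the primer-borne CTGGAG — i.e. exactly at
the far end of the 16-nt T tract — so the retained double-stranded cDNA
drops the primer head and the T tract.  Internal CTGGAG sites are protected
(hemimethylation) and never cut.  A configurable residual fraction escapes
digestion and keeps the full primer.  No PCR duplicates are simulated (the
cDNA protocol deliberately avoids amplification); per-transcript sampling
weights model expression level instead.

Reads: 454-style single-end reads (~246 bp mean) with per-base
substitutions, homopolymer-length-weighted single-base indels, and a
chimera fraction joining two fragments.  Every read carries a truth record
(individual, fragment, planted variants covered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_seq import (DEFAULT_ENZYMES, RestrictionEnzyme, digest,
                       reverse_complement)
from .panel import PanelEntry, TagPrimerPanel, table1_panel

logger = logging.getLogger(__name__)

#: Head of the modified oligo(dT) primer; carries the GsuI site CTGGAG.
OLIGODT_HEAD = "GAGAGAGAGACTGGAG"
OLIGODT_T_RUN = 16

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# configuration dataclasses

@dataclass(frozen=True)
class PanelDesign:
    """Study design for the genomic panel: 3 lines x 2 individuals by default."""

    n_lines: int = 3
    individuals_per_line: int = 2
    genome_length: int = 300_000
    snp_rate: float = 0.002           # per-bp probability of a planted variant
    line_specific_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be at least 1 kb")
        for r in (self.snp_rate, self.line_specific_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class SizeSelection:
    """Gel cut: [low, high] always kept; the extended window leaks through."""

    low: int = 200
    high: int = 400
    leak_prob: float = 0.1
    ext_low: int = 100
    ext_high: int = 500

    def __post_init__(self) -> None:
        if not self.ext_low <= self.low <= self.high <= self.ext_high:
            raise ValueError("size windows must nest: ext_low <= low <= high <= ext_high")


@dataclass(frozen=True)
class ReadModel:
    """454-style read error model.

    ``hp_indel_base`` is the per-homopolymer-run indel probability for a run
    of length 1; a run of length L gets min(1, hp_indel_base * (1 + hp_slope
    * (L - 1))), capturing the homopolymer-length dependence of 454 errors.
    """

    mean_len: float = 246.0
    len_sd: float = 40.0
    sub_rate: float = 0.002
    hp_indel_base: float = 0.0005
    hp_slope: float = 2.0
    chimera_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.hp_indel_base, self.chimera_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# truth containers

@dataclass(frozen=True)
class Variant:
    """A planted SNP, in ancestral coordinates (SNP-only, so shared by all)."""

    position: int
    ref: str
    alt: str
    carriers: frozenset[tuple[str, int]]   # (individual_id, haplotype index)
    line_specific: bool
    line_id: str | None = None             # set when line_specific


@dataclass(frozen=True)
class PanelGenomes:
    ancestor: str
    # individual_id -> (hap0, hap1)
    individuals: dict[str, tuple[str, str]]
    lines: dict[str, str]                  # individual_id -> line_id
    variants: tuple[Variant, ...]


@dataclass(frozen=True)
class Amplicon:
    """A tagged AFLP amplicon (or cDNA product) ready for read simulation."""

    sequence: str
    individual_id: str
    line_id: str
    fragment_id: str
    tag: str = ""
    weight: float = 1.0
    # (variant, offset of the variant base within `sequence`, carries_alt);
    # every panel variant inside the fragment interval is listed, so truth
    # records both alt- and ref-allele coverage of planted sites
    variants: tuple[tuple[Variant, int, bool], ...] = ()


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    individual_id: str
    line_id: str
    fragment_id: str                      # "a|b" for chimeras
    is_chimera: bool
    # planted-variant sites covered by the read, as "pos:ref>alt:alt" when
    # the read carries the alternate allele and "pos:ref>alt:ref" otherwise
    variants: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    truth: ReadTruth


# ---------------------------------------------------------------------------
# genome panel simulation

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_panel(design: PanelDesign,
                   panel: TagPrimerPanel | None = None) -> PanelGenomes:
    """Simulate per-individual diploid genomes with a truth variant table.

    One ancestral sequence is drawn; variant positions are sampled at
    ``snp_rate`` per bp.  A ``line_specific_fraction`` of variants is fixed
    (both haplotypes, both individuals) within exactly one line; the rest
    segregate at a random frequency across all haplotypes, re-drawn if the
    carrier set is empty or confined to a single line, so the truth flags
    stay exact.  Substitutions only: coordinates remain ancestral.
    """
    if panel is None:
        panel = table1_panel(design.n_lines, design.individuals_per_line)
    inds = list(panel.individuals)
    lines = {e.individual_id: e.line_id for e in panel.entries}
    line_ids = sorted(set(lines.values()))
    rng = np.random.default_rng(design.seed)
    ancestor = _random_seq(rng, design.genome_length)

    n_var = rng.binomial(design.genome_length, design.snp_rate)
    positions = np.sort(rng.choice(design.genome_length, size=n_var, replace=False))
    haplos = [(ind, h) for ind in inds for h in (0, 1)]
    variants: list[Variant] = []
    for pos in positions:
        ref = ancestor[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if rng.random() < design.line_specific_fraction:
            line = str(rng.choice(line_ids))
            carriers = frozenset((ind, h) for ind, h in haplos if lines[ind] == line)
            variants.append(Variant(int(pos), ref, alt, carriers, True, line))
        else:
            while True:
                freq = rng.uniform(0.2, 0.8)
                mask = rng.random(len(haplos)) < freq
                carriers = frozenset(hp for hp, m in zip(haplos, mask) if m)
                carrier_lines = {lines[ind] for ind, _ in carriers}
                if len(carrier_lines) >= 2:
                    break
            variants.append(Variant(int(pos), ref, alt, carriers, False))

    genomes: dict[str, tuple[str, str]] = {}
    for ind in inds:
        haps = []
        for h in (0, 1):
            arr = bytearray(ancestor, "ascii")
            for v in variants:
                if (ind, h) in v.carriers:
                    arr[v.position] = ord(v.alt)
            haps.append(arr.decode())
        genomes[ind] = (haps[0], haps[1])
    return PanelGenomes(ancestor, genomes, lines, tuple(variants))


# ---------------------------------------------------------------------------
# AFLP amplicon construction

#: Retained digestion-fragment end-label classes (enzyme-name pairs, unordered).
DEFAULT_CLASSES = frozenset({frozenset({"EcoRI", "TaqI"})})
ALL_CLASSES = DEFAULT_CLASSES | {frozenset({"EcoRI"}), frozenset({"TaqI"})}


def make_aflp_amplicons(genomes: PanelGenomes, entry: PanelEntry,
                        enzymes: list[RestrictionEnzyme] | None = None,
                        classes: frozenset[frozenset[str]] = DEFAULT_CLASSES,
                        ) -> list[Amplicon]:
    """Tagged preamplification amplicons for one individual.

    Both haplotypes are digested; for each retained fragment the amplicon is
    ``full_tagged_primer(left end) + insert + revcomp(full_tagged_primer(right
    end))``, both primers bearing the entry's tag.  By default only Eco-Taq
    fragments amplify (classic AFLP); Eco-Eco/Taq-Taq retention is opted in
    via ``classes``.  Fragments with an unlabeled (molecule-terminal) end are
    excluded.
    """
    if enzymes is None:
        enzymes = [DEFAULT_ENZYMES["EcoRI"], DEFAULT_ENZYMES["TaqI"]]
    primer_for = {"EcoRI": entry.eco_primer, "TaqI": entry.taq_primer}
    out: list[Amplicon] = []
    for h, hap_seq in enumerate(genomes.individuals[entry.individual_id]):
        for frag in digest(hap_seq, enzymes, source_id=f"{entry.individual_id}:h{h}"):
            if frag.left_end == "none" or frag.right_end == "none":
                logger.debug("terminal fragment %s:%d-%d excluded",
                             frag.source_id, frag.start, frag.end)
                continue
            if frozenset({frag.left_end, frag.right_end}) not in classes:
                continue
            left, right = primer_for[frag.left_end], primer_for[frag.right_end]
            seq = left + frag.sequence + reverse_complement(right)
            covered = tuple(
                (v, len(left) + v.position - frag.start,
                 (entry.individual_id, h) in v.carriers)
                for v in genomes.variants
                if frag.start <= v.position < frag.end
            )
            out.append(Amplicon(seq, entry.individual_id, entry.line_id,
                                f"{entry.individual_id}:h{h}:{frag.start}-{frag.end}",
                                tag=entry.tag, variants=covered))
    return out


def size_select(amplicons: list[Amplicon], sel: SizeSelection,
                seed: int | np.random.Generator = 0) -> list[Amplicon]:
    """Gel size selection with leakage.

    Lengths inside [low, high] are always kept; lengths inside the extended
    window but outside the nominal one are kept with ``leak_prob``; lengths
    outside the extended window never pass.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept = []
    for a in amplicons:
        n = len(a.sequence)
        if sel.low <= n <= sel.high:
            kept.append(a)
        elif sel.ext_low <= n <= sel.ext_high and rng.random() < sel.leak_prob:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# cDNA synthesis with GsuI polyA trimming

@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    sequence: str          # RNA-sense as DNA text, polyA tail included
    weight: float = 1.0    # expression level; read frequency is proportional


def simulate_transcripts(n: int, mean_len: int = 800, polya_mean: int = 50,
                         seed: int | np.random.Generator = 0,
                         internal_gsui_ok: bool = True) -> list[Transcript]:
    """Random polyadenylated transcripts with log-normal expression weights.

    Body lengths are normal around ``mean_len`` (min 100); tail lengths are
    geometric with the given mean, so a minority of tails fall below the
    16 nt the anchored primer needs — those transcripts yield no product,
    as in the protocol.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n):
        body_len = max(100, int(rng.normal(mean_len, mean_len / 4)))
        body = _random_seq(rng, body_len)
        if body.endswith("A"):  # keep the tail boundary unambiguous
            body = body[:-1] + str(rng.choice(list("CGT")))
        if not internal_gsui_ok:
            body = body.replace("CTGGAG", "CTGGAC").replace(
                reverse_complement("CTGGAG"), "GTCCAG")
        tail = int(rng.geometric(1.0 / polya_mean))
        weight = float(rng.lognormal(0.0, 1.0))
        out.append(Transcript(f"tx{i:05d}", body + "A" * tail, weight))
    return out


def _polya_tail_len(seq: str) -> int:
    n = 0
    for b in reversed(seq):
        if b != "A":
            break
        n += 1
    return n


def synthesize_trimmed_cdna(transcript: Transcript, uncut_prob: float = 0.0,
                            seed: int | np.random.Generator = 0,
                            ) -> Amplicon | None:
    """First-strand synthesis with the anchored oligo(dT) primer + GsuI trim.

    The primer's (T)16VN anchors at the 5' end of the polyA tail, so the
    first-strand cDNA reads ``GAGAGAGAGACTGGAG + T16 + revcomp(body)`` where
    *body* is the transcript minus its tail (the VN dinucleotide pairs with
    the last two body bases and ends up at the product 5' junction).  GsuI
    cleaves 16 nt downstream of the primer-borne CTGGAG — the far edge of
    the T tract — so the trimmed product is exactly ``revcomp(body)``.
    Internal CTGGAG sites are hemimethylation-protected and never cut.  With
    probability ``uncut_prob`` digestion fails and the product keeps the
    full primer (residual-primer flag set via fragment id suffix ``:uncut``).

    Returns None (logged) for transcripts whose tail is shorter than 16 nt.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tail = _polya_tail_len(transcript.sequence)
    if tail < OLIGODT_T_RUN:
        logger.info("transcript %s polyA tail %d < %d nt: no product",
                    transcript.transcript_id, tail, OLIGODT_T_RUN)
        return None
    body = transcript.sequence[:len(transcript.sequence) - tail]
    first_strand = reverse_complement(body)
    if rng.random() < uncut_prob:
        seq = OLIGODT_HEAD + "T" * OLIGODT_T_RUN + first_strand
        frag_id = f"{transcript.transcript_id}:uncut"
    else:
        seq = first_strand
        frag_id = transcript.transcript_id
    return Amplicon(seq, individual_id="pool", line_id="pool",
                    fragment_id=frag_id, weight=transcript.weight)


def make_cdna_library(transcripts: list[Transcript], uncut_prob: float = 0.02,
                      seed: int | np.random.Generator = 0) -> list[Amplicon]:
    """GsuI-trimmed double-stranded cDNA pool from a transcript set."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for tx in transcripts:
        prod = synthesize_trimmed_cdna(tx, uncut_prob, rng)
        if prod is not None:
            out.append(prod)
    return out


# ---------------------------------------------------------------------------
# 454-style read simulation

def _covered_variants(amp: Amplicon, start: int, end: int) -> tuple[str, ...]:
    return tuple(f"{v.position}:{v.ref}>{v.alt}:{'alt' if carried else 'ref'}"
                 for v, off, carried in amp.variants if start <= off < end)


def _apply_errors(seq: str, model: ReadModel, rng: np.random.Generator) -> str:
    if model.sub_rate > 0:
        arr = bytearray(seq, "ascii")
        hits = np.nonzero(rng.random(len(arr)) < model.sub_rate)[0]
        for i in hits:
            cur = chr(arr[i])
            arr[i] = ord(str(rng.choice([b for b in "ACGT" if b != cur])))
        seq = arr.decode()
    if model.hp_indel_base > 0 and seq:
        pieces: list[str] = []
        i = 0
        n = len(seq)
        while i < n:
            j = i
            while j < n and seq[j] == seq[i]:
                j += 1
            run = seq[i:j]
            p = min(1.0, model.hp_indel_base * (1 + model.hp_slope * (len(run) - 1)))
            if rng.random() < p:
                run = run + run[0] if rng.random() < 0.5 else run[:-1]
            pieces.append(run)
            i = j
        seq = "".join(pieces)
    return seq


def simulate_reads(fragments: list[Amplicon], model: ReadModel,
                   n_reads: int, seed: int | np.random.Generator | None = None,
                   read_prefix: str = "read") -> list[SimulatedRead]:
    """Sample 454-style reads with truth records.

    Fragments are sampled with replacement, weighted by ``weight`` (so cDNA
    read frequency tracks expression).  Each read starts at one end of the
    template (either strand, equiprobable) and extends to a normal-length
    draw or the template end, whichever is shorter.  With probability
    ``chimera_rate`` the read instead splices the 5' part of one fragment to
    the 3' part of another.  Substitutions and homopolymer-weighted
    single-base indels are then applied.
    """
    if not fragments:
        raise ValueError("empty fragment pool")
    if seed is None:
        seed = model.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([f.weight for f in fragments], dtype=float)
    weights /= weights.sum()
    reads: list[SimulatedRead] = []
    for k in range(n_reads):
        rid = f"{read_prefix}{k:06d}"
        length = max(30, int(rng.normal(model.mean_len, model.len_sd)))
        if len(fragments) >= 2 and rng.random() < model.chimera_rate:
            ia, ib = rng.choice(len(fragments), size=2, replace=False, p=weights)
            fa, fb = fragments[ia], fragments[ib]
            cut = int(rng.uniform(0.3, 0.7) * length)
            head = fa.sequence[:min(cut, len(fa.sequence))]
            tail_len = min(length - len(head), len(fb.sequence))
            tail = fb.sequence[len(fb.sequence) - tail_len:]
            raw = head + tail
            truth = ReadTruth(rid, fa.individual_id, fa.line_id,
                              f"{fa.fragment_id}|{fb.fragment_id}", True,
                              _covered_variants(fa, 0, len(head)))
        else:
            fi = int(rng.choice(len(fragments), p=weights))
            f = fragments[fi]
            forward = bool(rng.random() < 0.5)
            L = min(length, len(f.sequence))
            if forward:
                raw = f.sequence[:L]
                span = (0, L)
            else:
                raw = reverse_complement(f.sequence)[:L]
                span = (len(f.sequence) - L, len(f.sequence))
            truth = ReadTruth(rid, f.individual_id, f.line_id, f.fragment_id,
                              False, _covered_variants(f, *span))
        reads.append(SimulatedRead(rid, _apply_errors(raw, model, rng), truth))
    return reads
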