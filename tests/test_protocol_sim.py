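"""Synthetic-data generator: panel genomes, amplicons, cDNA trim, reads."""

import dataclasses
import math

import numpy as np
import pytest

from rrl454.core_seq import DEFAULT_ENZYMES, digest, iupac_find, reverse_complement
from rrl454.panel import table1_panel
from rrl454.protocol_sim import (OLIGODT_HEAD, Amplicon, PanelDesign,
                                 ReadModel, SizeSelection, Transcript,
                                 make_aflp_amplicons, make_cdna_library,
                                 simulate_panel, simulate_reads,
                                 simulate_transcripts, size_select,
                                 synthesize_trimmed_cdna)


class TestSimulatePanel:
    def test_snp_rate_zero_all_identical(self):
        g = simulate_panel(PanelDesign(genome_length=5000, snp_rate=0.0, seed=1))
        assert g.variants == ()
        for haps in g.individuals.values():
            assert haps[0] == g.ancestor and haps[1] == g.ancestor

    def test_three_lines_two_individuals_six_genomes(self):
        g = simulate_panel(PanelDesign(seed=2, genome_length=2000))
        assert len(g.individuals) == 6
        assert len(set(g.lines.values())) == 3
        assert all(len(h) == 2 for h in g.individuals.values())

    def test_variant_count_binomial(self):
        L, p, n_seeds = 30_000, 0.002, 20
        total = sum(len(simulate_panel(PanelDesign(genome_length=L, snp_rate=p,
                                                   seed=s)).variants)
                    for s in range(n_seeds))
        mean, sd = n_seeds * L * p, math.sqrt(n_seeds * L * p * (1 - p))
        assert abs(total - mean) <= 3 * sd

    def test_line_specific_variants_fixed_in_one_line(self):
        g = simulate_panel(PanelDesign(genome_length=50_000, seed=3))
        assert any(v.line_specific for v in g.variants)
        for v in g.variants:
            carrier_lines = {g.lines[ind] for ind, _h in v.carriers}
            if v.line_specific:
                assert carrier_lines == {v.line_id}
                # fixed: both haplotypes of both individuals of that line
                assert len(v.carriers) == 4
            else:
                assert len(carrier_lines) >= 2

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            PanelDesign(genome_length=500)


class TestAflpAmplicons:
    def test_tagged_primer_flanks(self, panel):
        g = simulate_panel(PanelDesign(genome_length=60_000, snp_rate=0.0, seed=4),
                           panel)
        entry = panel.by_tag("TACG")
        amps = make_aflp_amplicons(g, entry)
        assert amps
        eco, taq = "TACGCTGCGTTACCAATTCA", "TACGGATGAGTCCTGACCGAA"
        for a in amps:
            starts_eco = a.sequence.startswith(eco)
            starts_taq = a.sequence.startswith(taq)
            assert starts_eco or starts_taq
            if starts_eco:
                assert a.sequence.endswith(reverse_complement(taq))
            else:
                assert a.sequence.endswith(reverse_complement(eco))
        assert any(a.sequence.startswith(eco) for a in amps)

    def test_amplicon_count_matches_digest_census(self, panel):
        g = simulate_panel(PanelDesign(genome_length=60_000, snp_rate=0.0, seed=4),
                           panel)
        entry = panel.by_tag("TAGA")
        amps = make_aflp_amplicons(g, entry)
        enz = [DEFAULT_ENZYMES["EcoRI"], DEFAULT_ENZYMES["TaqI"]]
        expected = 0
        for hap in g.individuals[entry.individual_id]:
            frags = digest(hap, enz)
            expected += sum({f.left_end, f.right_end} == {"EcoRI", "TaqI"}
                            for f in frags)
        assert len(amps) == expected


class TestSizeSelect:
    def _amps(self, lengths):
        return [Amplicon("A" * n, "i", "l", f"f{k}") for k, n in enumerate(lengths)]

    def test_leak_zero_strict_window(self):
        sel = SizeSelection(leak_prob=0.0)
        kept = size_select(self._amps(range(50, 600, 7)), sel, seed=1)
        assert kept and all(200 <= len(a.sequence) <= 400 for a in kept)

    def test_extended_window_bounds(self):
        sel = SizeSelection(leak_prob=1.0)
        kept = size_select(self._amps(range(50, 600, 7)), sel, seed=1)
        assert all(100 <= len(a.sequence) <= 500 for a in kept)
        assert any(len(a.sequence) < 200 for a in kept)

    def test_leak_fraction_binomial(self):
        # lengths uniformly in the leak-only bands [100,200) and (400,500]
        lengths = list(range(100, 200)) + list(range(401, 501))
        sel = SizeSelection(leak_prob=0.3)
        kept = 0
        n = 0
        for seed in range(10):
            kept += len(size_select(self._amps(lengths), sel, seed=seed))
            n += len(lengths)
        sd = math.sqrt(n * 0.3 * 0.7)
        assert abs(kept - 0.3 * n) <= 3 * sd

    def test_bad_windows_rejected(self):
        with pytest.raises(ValueError):
            SizeSelection(low=150, high=400, ext_low=200, ext_high=500)


class TestCdnaSynthesis:
    body = ("TGCATGCACGTACGTTAGCATCGGATCGATCGTTAGCATGCGT" * 6)[:250] + "GC"

    def _tx(self, tail=30):
        return Transcript("t1", self.body + "A" * tail)

    def test_uncut_retains_full_primer(self):
        prod = synthesize_trimmed_cdna(self._tx(), uncut_prob=1.0, seed=0)
        assert OLIGODT_HEAD in prod.sequence
        assert prod.fragment_id.endswith(":uncut")
        assert prod.sequence == OLIGODT_HEAD + "T" * 16 + reverse_complement(self.body)

    def test_trimmed_product_drops_head_and_t_tract(self):
        prod = synthesize_trimmed_cdna(self._tx(), uncut_prob=0.0, seed=0)
        assert prod.sequence == reverse_complement(self.body)
        assert "CTGGAG" + "T" * 16 not in prod.sequence
        # the VN junction: first product base complements the last body base
        assert prod.sequence[0] == reverse_complement(self.body[-1])

    def test_internal_gsui_site_protected(self):
        body = self.body[:100] + "CTGGAG" + self.body[100:]
        tx = Transcript("t2", body + "A" * 40)
        prod = synthesize_trimmed_cdna(tx, uncut_prob=0.0, seed=0)
        # hemimethylation: product is the full reverse-complemented body,
        # internal site intact and uncleaved
        assert prod.sequence == reverse_complement(body)
        assert reverse_complement("CTGGAG") in prod.sequence

    def test_short_tail_yields_no_product(self):
        assert synthesize_trimmed_cdna(self._tx(tail=10), seed=0) is None

    def test_library_residual_fraction(self):
        tx = simulate_transcripts(400, seed=5)
        lib = make_cdna_library(tx, uncut_prob=0.1, seed=6)
        frac = sum(a.fragment_id.endswith(":uncut") for a in lib) / len(lib)
        sd = math.sqrt(0.1 * 0.9 / len(lib))
        assert abs(frac - 0.1) <= 3 * sd


class TestSimulateReads:
    frag = Amplicon("ACGTTGCA" * 40, "L1-1", "L1", "fragA")

    def test_error_free_long_reads_equal_fragment(self):
        model = ReadModel(mean_len=1000, len_sd=0.1, sub_rate=0, hp_indel_base=0,
                          chimera_rate=0, seed=1)
        reads = simulate_reads([self.frag], model, 50)
        for r in reads:
            assert r.sequence in (self.frag.sequence,
                                  reverse_complement(self.frag.sequence))
            assert not r.truth.is_chimera

    def test_chimera_fraction_binomial(self):
        frags = [dataclasses.replace(self.frag, fragment_id=f"f{i}",
                                     sequence=self.frag.sequence[i:] + "ACGT" * i)
                 for i in range(5)]
        model = ReadModel(sub_rate=0, hp_indel_base=0, chimera_rate=0.1, seed=2)
        reads = simulate_reads(frags, model, 4000)
        n_chim = sum(r.truth.is_chimera for r in reads)
        sd = math.sqrt(4000 * 0.1 * 0.9)
        assert abs(n_chim - 400) <= 3 * sd
        for r in reads:
            if r.truth.is_chimera:
                assert len(r.truth.fragment_id.split("|")) == 2

    def test_homopolymer_indels_increase_with_run_length(self):
        seq = "CCGGTT" + "A" * 10 + "GGCCTT" + "A" * 2 + "TTGGCC"
        frag = Amplicon(seq, "i", "l", "f")
        model = ReadModel(mean_len=100, len_sd=0.1, sub_rate=0,
                          hp_indel_base=0.02, hp_slope=1.0, chimera_rate=0, seed=3)
        reads = simulate_reads([frag], model, 10_000)
        long_changed = short_changed = 0
        for r in reads:
            s = r.sequence if r.sequence.startswith("CC") else reverse_complement(r.sequence)
            left, _, rest = s.partition("GGCCTT")
            long_changed += left != "CCGGTT" + "A" * 10
            short_changed += rest != "A" * 2 + "TTGGCC"
        assert long_changed > short_changed > 0

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        from rrl454 import io
        model = ReadModel(seed=9)
        outs = []
        for run in (1, 2):
            reads = simulate_reads([self.frag], model, 200, seed=9)
            fq = tmp_path / f"r{run}.fastq"
            tt = tmp_path / f"t{run}.tsv"
            io.write_fastq(((r.read_id, r.sequence) for r in reads), fq)
            io.write_truth(reads, tt)
            outs.append((fq.read_bytes(), tt.read_bytes()))
        assert outs[0] == outs[1]

    def test_truth_ids_unique_and_complete(self, small_sim):
        ids = [r.read_id for r in small_sim["reads"]]
        assert len(ids) == len(set(ids)) == len(small_sim["truth"])

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads([], ReadModel(), 10)

    def test_line_specific_truth_confined_to_line(self, small_sim):
        genomes = small_sim["genomes"]
        ls = {f"{v.position}:{v.ref}>{v.alt}": v.line_id
              for v in genomes.variants if v.line_specific}
        for t in small_sim["truth"].values():
            if t.is_chimera:
                continue
            for vstr in t.variants:
                key, allele = vstr.rsplit(":", 1)
                if allele == "alt" and key in ls:
                    assert t.line_id == ls[key]
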