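"""Greedy clustering, SNP candidates and their reports."""

import numpy as np
import pytest

from rrl454.cluster_snp import (ReadCluster, best_offset_identity, call_snps,
                                cluster_reads, depth_summary, write_snp_tsv,
                                write_snp_vcf)
from rrl454.core_seq import reverse_complement

RNG = np.random.default_rng(17)


def _rand_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


# --- independent oracle: exhaustive all-pairs greedy clustering -------------

def _oracle_identity(a, b, min_overlap):
    """Plain exhaustive best-identity scan, written independently."""
    best = None
    for o in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        matches = overlap = 0
        for i in range(len(b)):
            j = o + i
            if 0 <= j < len(a):
                overlap += 1
                matches += a[j] == b[i]
        if overlap >= min_overlap:
            ident = matches / overlap
            if best is None or ident > best:
                best = ident
    return best


def oracle_cluster(reads, min_identity=0.95, min_overlap=50):
    ordered = sorted(reads, key=lambda r: (-len(r[1]), r[1], r[0]))
    seeds = []       # (seed_seq, [read ids])
    for rid, seq in ordered:
        joined = False
        for seed_seq, members in seeds:
            for oriented in (seq, reverse_complement(seq)):
                ident = _oracle_identity(seed_seq, oriented, min_overlap)
                if ident is not None and ident >= min_identity:
                    members.append(rid)
                    joined = True
                    break
            if joined:
                break
        if not joined:
            seeds.append((seq, [rid]))
    return {frozenset(m) for _s, m in seeds}


def _memberships(clusters, singlets):
    out = {frozenset(m.read_id for m in c.members) for c in clusters}
    out |= {frozenset([s]) for s in singlets}
    return out


class TestClusterReads:
    def test_identical_reads_single_cluster(self):
        seq = _rand_seq(150)
        reads = [(f"r{i}", seq) for i in range(10)]
        clusters, singlets = cluster_reads(reads)
        assert len(clusters) == 1 and clusters[0].depth == 10
        assert singlets == []
        assert clusters[0].consensus == seq

    def test_two_distant_loci_two_clusters(self):
        a, b = _rand_seq(200), _rand_seq(200)
        reads = [(f"a{i}", a) for i in range(5)] + [(f"b{i}", b) for i in range(5)]
        clusters, singlets = cluster_reads(reads)
        assert len(clusters) == 2 and not singlets
        assert {frozenset(m.read_id for m in c.members) for c in clusters} == \
            {frozenset(f"a{i}" for i in range(5)), frozenset(f"b{i}" for i in range(5))}

    def test_reverse_strand_reads_join(self):
        seq = _rand_seq(180)
        reads = [("f", seq), ("r", reverse_complement(seq)), ("f2", seq[10:170])]
        clusters, singlets = cluster_reads(reads)
        assert len(clusters) == 1 and clusters[0].depth == 3

    def test_matches_all_pairs_oracle(self):
        """Exact membership agreement with the exhaustive greedy oracle."""
        rng = np.random.default_rng(5)
        loci = [_rand_seq(rng.integers(150, 300), rng) for _ in range(6)]
        reads = []
        for k in range(48):
            locus = loci[int(rng.integers(len(loci)))]
            # truncated copies with sparse substitutions, either strand
            start = int(rng.integers(0, max(1, len(locus) - 120)))
            sub = list(locus[start:start + int(rng.integers(120, 260))])
            for i in range(len(sub)):
                if rng.random() < 0.002:
                    sub[i] = "ACGT"[int(rng.integers(4))]
            s = "".join(sub)
            if rng.random() < 0.5:
                s = reverse_complement(s)
            reads.append((f"r{k:02d}", s))
        clusters, singlets = cluster_reads(reads)
        assert _memberships(clusters, singlets) == oracle_cluster(reads)

    def test_deterministic_under_input_order(self):
        rng = np.random.default_rng(9)
        locus = _rand_seq(220, rng)
        reads = [(f"r{i}", locus[int(rng.integers(0, 40)):]) for i in range(20)]
        m1 = _memberships(*cluster_reads(reads))
        m2 = _memberships(*cluster_reads(list(reversed(reads))))
        assert m1 == m2

    def test_best_offset_identity_basic(self):
        a = _rand_seq(140)
        ident, off = best_offset_identity(a, a[8:100], min_overlap=50)
        assert ident == 1.0 and off == 8


def _make_cluster(columns_by_read):
    """Build a ReadCluster directly from aligned same-length reads."""
    clusters, singlets = cluster_reads(
        [(rid, seq) for rid, seq in columns_by_read], min_overlap=30)
    assert len(clusters) == 1 and not singlets
    return clusters[0]


class TestCallSnps:
    # ref allele "A" sorts before alt "C": consensus tie-breaks stay on ref
    base = _rand_seq(120)[:60] + "A" + _rand_seq(59)

    def _variant_reads(self, n_ref, n_alt, pos=60, alt="C"):
        ref_seq = self.base
        alt_seq = ref_seq[:pos] + alt + ref_seq[pos + 1:]
        reads = [(f"ref{i}", ref_seq) for i in range(n_ref)]
        reads += [(f"alt{i}", alt_seq) for i in range(n_alt)]
        return reads, pos

    def test_homogeneous_cluster_no_candidates(self):
        cl = _make_cluster([(f"r{i}", self.base) for i in range(6)])
        assert call_snps(cl, {f"r{i}": "A" for i in range(6)},
                         {"A": "L1"}) == []

    def test_biallelic_across_lines_not_line_specific(self):
        reads, pos = self._variant_reads(3, 3)
        cl = _make_cluster(reads)
        ind_of = {"ref0": "L1-1", "ref1": "L1-2", "ref2": "L2-1",
                  "alt0": "L2-2", "alt1": "L3-1", "alt2": "L3-2"}
        line_of = {f"L{i}-{j}": f"L{i}" for i in (1, 2, 3) for j in (1, 2)}
        line_of = {v: v.split("-")[0] for v in ind_of.values()}
        cands = call_snps(cl, ind_of, line_of)
        assert len(cands) == 1
        c = cands[0]
        assert c.offset == pos and not c.line_specific
        assert c.allele_depths["L1-1"] == (1, 0)
        assert c.allele_depths["L3-1"] == (0, 1)

    def test_line_specific_variant_flagged(self):
        reads, pos = self._variant_reads(4, 4)
        cl = _make_cluster(reads)
        ind_of = {"ref0": "L2-1", "ref1": "L2-2", "ref2": "L3-1", "ref3": "L3-2",
                  "alt0": "L1-1", "alt1": "L1-1", "alt2": "L1-2", "alt3": "L1-2"}
        line_of = {v: v.split("-")[0] for v in ind_of.values()}
        cands = call_snps(cl, ind_of, line_of)
        assert len(cands) == 1 and cands[0].line_specific
        assert set(cands[0].alt_reads) == {"alt0", "alt1", "alt2", "alt3"}

    def test_single_individual_support_rejected(self):
        reads, _pos = self._variant_reads(3, 3)
        cl = _make_cluster(reads)
        ind_of = {rid: "L1-1" for rid, _ in reads}
        assert call_snps(cl, ind_of, {"L1-1": "L1"}) == []

    def test_min_allele_reads_threshold(self):
        reads, _pos = self._variant_reads(4, 1)
        cl = _make_cluster(reads)
        ind_of = {"ref0": "L1-1", "ref1": "L1-2", "ref2": "L2-1", "ref3": "L2-2",
                  "alt0": "L3-1"}
        line_of = {v: v.split("-")[0] for v in ind_of.values()}
        assert call_snps(cl, ind_of, line_of) == []

    def test_triallelic_column_skipped(self):
        pos = 60
        seqs = {}
        for allele, n in (("A", 2), ("C", 2), ("G", 2)):
            s = self.base[:pos] + allele + self.base[pos + 1:]
            for i in range(n):
                seqs[f"{allele}{i}"] = s
        cl = _make_cluster(list(seqs.items()))
        ind_of = {rid: f"L{i % 3 + 1}-1" for i, rid in enumerate(seqs)}
        line_of = {v: v.split("-")[0] for v in ind_of.values()}
        cands = call_snps(cl, ind_of, line_of)
        assert all(c.offset != pos for c in cands)

    def test_shallow_cluster_skipped(self):
        reads, _pos = self._variant_reads(2, 1)
        cl = _make_cluster(reads)
        assert call_snps(cl, {r: "A" for r, _ in reads}, {"A": "L1"},
                         min_allele_reads=2) == []


class TestDepthSummaryAndWriters:
    def test_summary_example(self):
        clusters = [ReadCluster(i, [None] * n) for i, n in enumerate((2, 3, 4))]
        d = depth_summary(clusters, [])
        assert (d.n_contigs, d.mean_depth, d.min_depth, d.max_depth) == (3, 3.0, 2, 4)

    def test_empty_no_division_error(self):
        d = depth_summary([], ["a", "b"])
        assert (d.n_contigs, d.n_singlets, d.mean_depth) == (0, 2, 0.0)

    def test_conservation_on_simulation(self, panel, small_sim):
        from rrl454.demux import demux_run
        res = demux_run(((r.read_id, r.sequence) for r in small_sim["reads"]), panel)
        trimmed = []
        for c in res.classifications:
            if c.category == "double_same":
                a, b = c.trimmed_interval
                seq = next(r.sequence for r in small_sim["reads"]
                           if r.read_id == c.read_id)
                trimmed.append((c.read_id, seq[a:b]))
        clusters, singlets = cluster_reads(trimmed[:800])
        d = depth_summary(clusters, singlets)
        assert sum(c.depth for c in clusters) + d.n_singlets == len(trimmed[:800])
        all_ids = [m.read_id for c in clusters for m in c.members] + singlets
        assert len(all_ids) == len(set(all_ids))

    def test_vcf_round_trips_through_cyvcf2(self, tmp_path):
        reads, pos = TestCallSnps()._variant_reads(3, 3)
        cl = _make_cluster(reads)
        ind_of = {"ref0": "L1-1", "ref1": "L1-2", "ref2": "L2-1",
                  "alt0": "L1-1", "alt1": "L1-2", "alt2": "L2-1"}
        line_of = {v: v.split("-")[0] for v in ind_of.values()}
        cands = call_snps(cl, ind_of, line_of)
        vcf_path = tmp_path / "c.vcf"
        write_snp_vcf(cands, [cl], vcf_path)
        write_snp_tsv(cands, tmp_path / "c.tsv")
        import cyvcf2
        recs = list(cyvcf2.VCF(str(vcf_path)))
        assert len(recs) == len(cands) == 1
        rec = recs[0]
        assert rec.POS == cands[0].offset + 1
        assert rec.REF == cands[0].ref_allele
        assert rec.ALT == [cands[0].alt_allele]
        assert rec.INFO.get("DP") == cands[0].depth
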