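"""RPKM, Audic-Claverie test, BH FDR, DE calling and GO enrichment."""
import numpy as np
import pandas as pd
import pytest

import tarscribe as ts
from tarscribe.expression import audic_claverie_p, bh_fdr, call_de, go_enrichment, mirna_de, rpkm
from tarscribe.model import AlignmentRecord, GeneModel, GenomicInterval

from oracles import bh_stepup, binomial_two_sided_p, hypergeom_upper_tail


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(10, 1000, 10**6, 10.0), (0, 1000, 10**6, 0.0), (250, 2500, 8_500_000, 11.76470588)],
    )
    def test_formula(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected, rel=1e-8)


class TestAudicClaverie:
    def test_no_counts_no_evidence(self):
        assert audic_claverie_p(0, 0, 1e6, 2e6) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            x, y = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            n1, n2 = float(rng.integers(1, 10) * 1e5), float(rng.integers(1, 10) * 1e5)
            assert audic_claverie_p(x, y, n1, n2) == pytest.approx(
                audic_claverie_p(y, x, n2, n1), abs=1e-12
            )

    def test_enumeration_oracle_example(self):
        # x=5, y=15, equal totals: doubled Binomial(20, 1/2) tails
        p = audic_claverie_p(5, 15, 1e6, 1e6)
        assert p == pytest.approx(binomial_two_sided_p(5, 15, 1, 1), abs=1e-12)
        assert p == pytest.approx(0.04138947, abs=1e-7)

    def test_unequal_library_sizes(self):
        for x, y in [(0, 10), (7, 3), (20, 45)]:
            assert audic_claverie_p(x, y, 1e6, 5e6) == pytest.approx(
                binomial_two_sided_p(x, y, 1, 5), abs=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            audic_claverie_p(1, 1, 0, 1e6)
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 1, 1e6, 1e6)


class TestBhFdr:
    def test_all_ones(self):
        assert (bh_fdr([1.0] * 5) == 1.0).all()

    def test_hand_stepup_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_stepup_random(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1, size=50)
        assert bh_fdr(p) == pytest.approx(bh_stepup(list(p)), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(21)
        p = rng.uniform(1e-6, 1, size=300)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_fdr(p) == pytest.approx(q_ref, abs=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(1e-6, 1, size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDe:
    def _tables(self, pairs):
        idx = [f"g{i}" for i in range(len(pairs))]
        a = pd.Series([p[0] for p in pairs], index=idx)
        b = pd.Series([p[1] for p in pairs], index=idx)
        return a, b

    def test_equal_counts_not_significant(self):
        a, b = self._tables([(100, 100), (7, 7)])
        df = call_de(a, b, 1e6, 1e6)
        assert (df.log2_ratio == 0).all() and not df.significant.any()

    def test_double_zero_excluded(self):
        a, b = self._tables([(0, 0), (5, 5)])
        df = call_de(a, b, 1e6, 1e6)
        assert list(df.gene_id) == ["g1"]

    def test_planted_fourfold_significant(self):
        a, b = self._tables([(400, 100)])
        df = call_de(a, b, 1e7, 1e7)
        assert df.significant.all() and df.direction[0] == "up"
        assert df.p[0] == pytest.approx(binomial_two_sided_p(400, 100, 1, 1), abs=1e-12)

    def test_swap_negates_ratio_keeps_p(self):
        rng = np.random.default_rng(4)
        a, b = self._tables([(int(x), int(y)) for x, y in rng.integers(0, 300, (50, 2))])
        d1 = call_de(a, b, 1e6, 1e6)
        d2 = call_de(b, a, 1e6, 1e6)
        assert d1.log2_ratio.values == pytest.approx(-d2.log2_ratio.values)
        assert d1.p.values == pytest.approx(d2.p.values)
        assert d1.q.values == pytest.approx(d2.q.values)

    def test_zero_in_one_library_finite_ratio(self):
        a, b = self._tables([(0, 40)])
        df = call_de(a, b, 1e6, 1e6)
        assert np.isfinite(df.log2_ratio[0]) and df.log2_ratio[0] < 0

    def test_mismatched_universe_errors(self):
        a = pd.Series([1], index=["g0"])
        b = pd.Series([1], index=["g1"])
        with pytest.raises(ValueError, match="g0"):
            call_de(a, b, 1e6, 1e6)


class TestMirnaDe:
    def test_thresholds(self):
        idx = ["m0", "m1", "m2"]
        a = pd.Series([300, 100, 500], index=idx)
        b = pd.Series([100, 100, 280], index=idx)
        df = mirna_de(a, b, 1e5, 1e5).set_index("gene_id")
        assert bool(df.loc["m0", "significant"])  # 3-fold, tiny p
        assert not bool(df.loc["m1", "significant"])  # equal
        # |log2fc| < 1 despite small p: both conditions required
        assert abs(df.loc["m2", "log2_ratio"]) < 1 and df.loc["m2", "p"] < 0.01
        assert not bool(df.loc["m2", "significant"])


class TestQuantify:
    def _annotation(self):
        def gene(gid, spans):
            exons = [GenomicInterval("chr1", s, e, "+") for s, e in spans]
            return GeneModel(
                gid, GenomicInterval("chr1", exons[0].start, exons[-1].end, "+"), exons
            )
        return [gene("g1", [(0, 500), (700, 1200)]), gene("g2", [(2000, 3000)])]

    def test_counts_and_rpkm(self):
        ann = self._annotation()
        reads = [
            AlignmentRecord(f"r{i}", 1, [GenomicInterval("chr1", 100, 190)]) for i in range(10)
        ]
        recs = ts.quantify(reads, ann, total_mapped=10**6)
        by_id = {r.gene_id: r for r in recs}
        assert by_id["g1"].count == 10 and by_id["g2"].count == 0
        assert by_id["g1"].rpkm == pytest.approx(10.0)  # 10 reads / 1 kb exon / 1 M
        assert by_id["g2"].rpkm == 0.0

    def test_ambiguous_read_unassigned(self):
        ann = self._annotation()
        # 45 bp on g1's exon end and 45 bp on g2 would tie; construct overlap tie
        read = AlignmentRecord(
            "tie", 1,
            [GenomicInterval("chr1", 455, 500), GenomicInterval("chr1", 2000, 2045)],
        )
        recs = ts.quantify([read], ann, total_mapped=100)
        assert all(r.count == 0 for r in recs)

    def test_assignment_conservation(self, dataset):
        recs = ts.quantify(dataset["alignments"], dataset["annotation"])
        n_unique = sum(1 for r in dataset["alignments"] if r.unique)
        assert 0 < sum(r.count for r in recs) <= n_unique


class TestGoEnrichment:
    def _fixture(self, k, K=10, n=10, N=100):
        background = [f"g{i}" for i in range(N)]
        de = background[:n]
        gene2go = {}
        # k DE genes and K-k non-DE genes carry the term
        for g in background[:k] + background[n:n + (K - k)]:
            gene2go[g] = [("GO:1", "biological process")]
        return de, gene2go, background

    @pytest.mark.parametrize("k", [1, 3, 5, 10])
    def test_enumeration_oracle(self, k):
        de, gene2go, bg = self._fixture(k)
        res = go_enrichment(de, gene2go, bg)
        assert len(res) == 1
        assert res[0].p_hyper == pytest.approx(hypergeom_upper_tail(100, 10, 10, k), abs=1e-12)
        assert res[0].p_bonferroni == pytest.approx(min(1.0, res[0].p_hyper), abs=1e-12)

    def test_term_without_de_gene_untested(self):
        de, gene2go, bg = self._fixture(0)
        assert go_enrichment(de, gene2go, bg) == []

    def test_empty_de_empty_result(self):
        assert go_enrichment([], {}, ["g1"]) == []

    def test_de_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(["gX"], {}, ["g1"])
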