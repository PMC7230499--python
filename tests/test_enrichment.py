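import math
from fractions import Fraction

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from foldsea import (
    AnnotationMap,
    ContingencyTable,
    FoldChangeInterval,
    RegulationList,
    adjust_pvalues,
    build_quantile_partition,
    compare_fsea_sea,
    contingency_table,
    enumerate_intervals,
    fisher_greater,
    n_intervals,
    run_fsea,
    run_sea,
)


def hypergeom_tail_bruteforce(A, B, C, D):
    """Exact P(X >= A) by summing the hypergeometric pmf with integer combs."""
    N, K, n = A + B + C + D, A + B, A + C
    total = 0
    for x in range(A, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return float(Fraction(total, math.comb(N, n)))


class TestQuantilePartition:
    def test_n_equals_k(self):
        reg = RegulationList("up", list("abcde"), np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
        part = build_quantile_partition(reg, 5)
        assert list(part.sizes) == [1, 1, 1, 1, 1]
        assert part.assignment == {g: i + 1 for i, g in enumerate("abcde")}

    def test_even_split(self):
        genes = [f"g{i}" for i in range(10)]
        reg = RegulationList("up", genes, np.arange(1, 11) / 10)
        part = build_quantile_partition(reg, 5)
        assert list(part.sizes) == [2, 2, 2, 2, 2]
        assert part.assignment["g0"] == 1 and part.assignment["g1"] == 1
        # boundaries are the |logFC| of the last gene of quantiles 1..4
        np.testing.assert_allclose(part.boundaries, [0.2, 0.4, 0.6, 0.8])

    def test_total_tie_uses_rank_rule(self):
        genes = sorted(f"g{i}" for i in range(10))
        reg = RegulationList("up", genes, np.ones(10))
        part = build_quantile_partition(reg, 5)
        assert list(part.sizes) == [2, 2, 2, 2, 2]

    def test_sizes_differ_by_at_most_one(self):
        reg = RegulationList("up", [f"g{i:02d}" for i in range(13)], np.arange(13.0))
        part = build_quantile_partition(reg, 5)
        assert part.sizes.sum() == 13
        assert part.sizes.max() - part.sizes.min() <= 1

    def test_errors(self):
        reg = RegulationList("up", list("abc"), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            build_quantile_partition(reg, 4)
        with pytest.raises(ValueError):
            build_quantile_partition(reg, 1)


class TestEnumerateIntervals:
    def test_k5_has_14(self):
        assert len(enumerate_intervals(5)) == 14

    def test_k2_k3_explicit(self):
        assert [(i.lo, i.hi) for i in enumerate_intervals(2)] == [(1, 1), (2, 2)]
        assert [(i.lo, i.hi) for i in enumerate_intervals(3)] == [
            (1, 1), (1, 2), (2, 2), (2, 3), (3, 3)]

    @pytest.mark.parametrize("k", range(2, 11))
    def test_count_formula(self, k):
        ivs = enumerate_intervals(k)
        assert len(ivs) == n_intervals(k) == k * (k + 1) // 2 - 1
        assert FoldChangeInterval(1, k) not in ivs
        assert len(set(ivs)) == len(ivs)

    def test_k1_errors(self):
        with pytest.raises(ValueError):
            enumerate_intervals(1)


class TestContingencyTable:
    def test_direct_enumeration(self):
        deg = {f"g{i}" for i in range(1, 11)}
        t = contingency_table({"g1", "g2"}, {"g1", "g2", "g3"}, deg)
        assert (t.A, t.B, t.C, t.D) == (2, 0, 1, 7)

    def test_term_disjoint_from_deg(self):
        t = contingency_table({"x", "y"}, {"g1"}, {"g1", "g2"})
        assert (t.A, t.B) == (0, 0)

    def test_interval_equals_deg(self):
        deg = {f"g{i}" for i in range(6)}
        term = {"g0", "g1"}
        t = contingency_table(term, deg, deg)
        assert (t.C, t.D) == (4, 0)

    def test_interval_outside_deg_errors(self):
        with pytest.raises(ValueError):
            contingency_table({"a"}, {"zzz"}, {"a", "b"})


class TestFisherGreater:
    @pytest.mark.parametrize(
        "cells,expected",
        [((2, 0, 0, 2), 1 / 6), ((0, 3, 4, 5), 1.0), ((5, 0, 0, 5), 1 / 252)],
    )
    def test_known_tables(self, cells, expected):
        assert fisher_greater(ContingencyTable(*cells)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            p = fisher_greater(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(hypergeom_tail_bruteforce(a, b, c, d), abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestAdjustPvalues:
    def test_bh_hand_example(self):
        adj = adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues(np.array([0.2]), method=method)[0] == 0.2

    def test_bonferroni_clips(self):
        assert adjust_pvalues(np.full(50, 0.04), method="bonferroni")[0] == 1.0

    def test_total_tests_mismatch_errors(self):
        with pytest.raises(ValueError, match="total_tests"):
            adjust_pvalues(np.array([0.1, 0.2]), total_tests=5)

    def test_bh_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = adjust_pvalues(p, method="bh")
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_shape_preserved(self):
        p = np.random.default_rng(0).uniform(size=(6, 14))
        assert adjust_pvalues(p, method="bh", total_tests=84).shape == (6, 14)


class TestRunFsea:
    def test_top_quantile_term_frozen_example(self, reg20, annotation_top4):
        """20 DEGs, k=2, a 4-gene term fully in the upper half."""
        res = run_fsea(reg20, annotation_top4, k=2)
        assert res.s == 1 and res.n_intervals == 2 and res.m == 2
        r = res.records[0]
        assert (r.best_interval.lo, r.best_interval.hi) == (2, 2)
        assert (r.table.A, r.table.B, r.table.C, r.table.D) == (4, 0, 6, 10)
        assert r.p_raw == pytest.approx(8008 / 184756, rel=1e-12)
        assert r.p_adj >= r.p_raw

    def test_uniform_term_not_significant(self, reg20):
        # one gene in every position-pair: uniform across any interval
        ann = AnnotationMap({"T": set(reg20.genes[::2]), "U": set(reg20.genes[1::2])})
        res = run_fsea(reg20, ann, k=5)
        assert res.significant_terms == set()
        assert all(r.p_adj <= 1.0 for r in res.records)

    def test_invariant_under_gene_renaming(self, reg20, annotation_top4):
        res0 = run_fsea(reg20, annotation_top4, k=5)
        rename = {g: f"X_{g}" for g in reg20.genes}
        reg2 = RegulationList(
            "up", [rename[g] for g in reg20.genes], reg20.abs_log_fc.copy()
        )
        ann2 = AnnotationMap(
            {"T": {rename[g] for g in annotation_top4.term_to_genes["T"]}}
        )
        res1 = run_fsea(reg2, ann2, k=5)
        assert [r.p_raw for r in res0.records] == [r.p_raw for r in res1.records]
        assert [r.p_adj for r in res0.records] == [r.p_adj for r in res1.records]

    def test_annotation_restricted_per_direction(self, reg20):
        ann = AnnotationMap({"T": set(reg20.genes[:3]), "GONE": {"not_a_deg"}})
        res = run_fsea(reg20, ann, k=2)
        assert res.s == 1  # GONE dropped, s and hence m shrink
        assert res.m == 2

    def test_no_testable_terms_errors(self, reg20):
        with pytest.raises(ValueError, match="no testable terms"):
            run_fsea(reg20, AnnotationMap({"T": {"absent"}}), k=2)

    def test_best_interval_minimizes_raw_p(self, reg20):
        rng = np.random.default_rng(11)
        terms = {
            f"T{i}": set(rng.choice(reg20.genes, size=6, replace=False))
            for i in range(5)
        }
        res = run_fsea(reg20, AnnotationMap(terms), k=4)
        part = build_quantile_partition(reg20, 4)
        for r in res.records:
            best = min(
                fisher_greater(
                    contingency_table(
                        AnnotationMap(terms).term_to_genes[r.term_id],
                        part.genes_in_interval(iv, reg20.genes),
                        reg20.gene_set,
                    )
                )
                for iv in enumerate_intervals(4)
            )
            assert r.p_raw == pytest.approx(best, abs=1e-12)

    def test_planted_signal_recovered(self):
        """A term concentrated in the top quantile of a 200-DEG list is
        flagged fold-change-specific in >= 90% of random instantiations,
        despite 20 decoy terms."""
        rng = np.random.default_rng(123)
        genes = [f"g{i:03d}" for i in range(200)]
        hits = 0
        n_trials = 40
        for _ in range(n_trials):
            values = np.sort(rng.normal(size=200) ** 2)
            reg = RegulationList("up", genes, values)
            planted = set(rng.choice(genes[160:], size=10, replace=False))
            terms = {"PLANTED": planted}
            for i in range(20):
                size = int(rng.integers(5, 30))
                terms[f"D{i}"] = set(rng.choice(genes, size=size, replace=False))
            res = run_fsea(reg, AnnotationMap(terms), k=5, fdr=0.05)
            hits += "PLANTED" in res.significant_terms
        assert hits / n_trials >= 0.9


class TestRunSea:
    def test_symmetric_example(self):
        universe = {f"g{i}" for i in range(20)}
        deg = {f"g{i}" for i in range(10)}
        ann = AnnotationMap({"T": {"g0", "g1", "g2", "g3"}})
        res = run_sea(deg, universe, ann)
        r = res.records[0]
        assert r.p_raw == pytest.approx(8008 / 184756, rel=1e-12)
        assert (r.deg_hits, r.deg_total, r.bg_hits, r.bg_total) == (4, 10, 4, 20)

    def test_zero_hit_term_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = run_sea({"g0"}, universe, AnnotationMap({"T": {"g5", "g6"}}))
        assert res.records[0].p_raw == 1.0

    def test_term_equal_to_universe_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        res = run_sea({"g0", "g1"}, universe, AnnotationMap({"T": set(universe)}))
        assert res.records[0].p_raw == 1.0

    def test_deg_outside_universe_errors(self):
        with pytest.raises(ValueError, match="subset"):
            run_sea({"x"}, {"a", "b"}, AnnotationMap({"T": {"a"}}))


class TestCompare:
    def test_three_way_partition(self):
        class Stub:
            def __init__(self, terms):
                self.significant_terms = set(terms)

        out = compare_fsea_sea(Stub({"T1", "T2"}), Stub({"T2", "T3"}))
        assert out["both"] == ["T2"]
        assert out["fsea_only"] == ["T1"]
        assert out["sea_only"] == ["T3"]
        assert out["n_both"] + out["n_fsea_only"] + out["n_sea_only"] == 3

    def test_empty_and_identical(self):
        class Stub:
            def __init__(self, terms):
                self.significant_terms = set(terms)

        empty = compare_fsea_sea(Stub(set()), Stub(set()))
        assert empty["both"] == empty["fsea_only"] == empty["sea_only"] == []
        same = compare_fsea_sea(Stub({"A"}), Stub({"A"}))
        assert same["fsea_only"] == [] and same["sea_only"] == []
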