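"""Scoring, the triangular index map, the exhaustive argmax and the greedy loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multihit import (
    SampleMask,
    SearchConfig,
    ValidationError,
    best_combination,
    classify_sample,
    cover_result_to_report,
    filter_gene_universe,
    greedy_cover,
    lambda_to_pair,
    naive_best_combination,
    naive_greedy_cover,
    pair_to_lambda,
    score_combination,
    upper_bound_f,
)

from conftest import pack_instance, random_instance


class TestScore:
    @pytest.mark.parametrize(
        "tp,tn,n_t,n_n,alpha,expected",
        [
            (10, 10, 10, 10, 0.1, 0.55),
            (0, 0, 10, 10, 0.1, 0.0),
            # hand evaluation: (0.1*7 + 93) / 125
            (7, 93, 25, 100, 0.1, 93.7 / 125),
        ],
    )
    def test_weighted_accuracy_values(self, tp, tn, n_t, n_n, alpha, expected):
        assert score_combination(tp, tn, n_t, n_n, alpha) == pytest.approx(
            expected, abs=1e-15
        )

    def test_validation(self):
        with pytest.raises(ValidationError):
            score_combination(0, 0, 0, 0, 0.1)
        with pytest.raises(ValidationError):
            score_combination(11, 0, 10, 10, 0.1)
        with pytest.raises(ValidationError):
            score_combination(0, 11, 10, 10, 0.1)


def _enumerate_pairs(n_genes):
    """Pairs in the lambda order: lam = j*(j-1)/2 + i."""
    return [(i, j) for j in range(n_genes) for i in range(j)]


class TestTriangularIndex:
    def test_first_pair(self):
        assert lambda_to_pair(0, 5) == (0, 1)

    def test_enumerated_order(self):
        # independent enumeration: (0,1),(0,2),(1,2),(0,3),(1,3),...
        assert _enumerate_pairs(5)[4] == (1, 3)
        assert lambda_to_pair(4, 5) == (1, 3)
        assert pair_to_lambda(1, 3) == 4

    def test_last_pair_boundary(self):
        g = 10
        assert lambda_to_pair(g * (g - 1) // 2 - 1, g) == (g - 2, g - 1)

    def test_bijection_exhaustive_g100(self):
        g = 100
        pairs = [lambda_to_pair(lam, g) for lam in range(g * (g - 1) // 2)]
        assert pairs == _enumerate_pairs(g)
        for lam, (i, j) in enumerate(pairs):
            assert pair_to_lambda(i, j) == lam

    def test_validation(self):
        with pytest.raises(ValidationError):
            lambda_to_pair(10, 5)
        with pytest.raises(ValidationError):
            lambda_to_pair(-1, 5)
        with pytest.raises(ValidationError):
            pair_to_lambda(3, 3)


class TestUpperBound:
    def test_no_coverage_bound(self):
        assert upper_bound_f(0, 25, 100, 0.1) == pytest.approx(100 / 125)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        tp=st.integers(0, 50),
        tn=st.integers(0, 80),
        extra=st.integers(0, 20),
    )
    def test_dominates_any_completion(self, tp, tn, extra):
        """The bound from a prefix TP dominates F of any completion (TP can
        only shrink, TN is at most N_n)."""
        n_t, n_n = 50, 80
        bound = upper_bound_f(tp + extra, n_t, n_n, 0.1)
        assert bound >= score_combination(tp, tn, n_t, n_n, 0.1)


def _assert_same_combination(a, b):
    assert a.gene_indices == b.gene_indices
    assert a.tp == b.tp and a.tn == b.tn
    assert a.f == pytest.approx(b.f, abs=1e-12)


def _assert_same_cover(a, b):
    assert len(a.combinations) == len(b.combinations)
    for x, y in zip(a.combinations, b.combinations):
        _assert_same_combination(x, y)
    assert a.uncovered_tumor_sample_ids == b.uncovered_tumor_sample_ids
    assert a.iterations == b.iterations


class TestBestCombination:
    def test_unique_perfect_pair(self):
        tumor = np.zeros((4, 1), dtype=np.uint8)
        tumor[[0, 1], 0] = 1
        normal = np.zeros((4, 6), dtype=np.uint8)
        t, n = pack_instance(tumor, normal, list("abcd"), ["T0"], [f"N{j}" for j in range(6)])
        best = best_combination(t, n, SampleMask.full(1), SearchConfig(h=2))
        assert best.gene_indices == (0, 1)
        assert best.tp == 1 and best.tn == 6

    def test_lexicographic_tie_break(self):
        # sample A mutated in {0,1}, sample B in {2,3}: tp ties at 1,
        # tn ties at N_n, so the smaller tuple (0,1) must win
        tumor = np.zeros((4, 2), dtype=np.uint8)
        tumor[[0, 1], 0] = 1
        tumor[[2, 3], 1] = 1
        normal = np.zeros((4, 5), dtype=np.uint8)
        t, n = pack_instance(tumor, normal, list("abcd"), ["A", "B"], [f"N{j}" for j in range(5)])
        best = best_combination(t, n, SampleMask.full(2), SearchConfig(h=2, alpha=0.1))
        assert best.gene_indices == (0, 1)

    def test_h3_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        tumor, normal, genes, t_ids, n_ids = random_instance(
            rng, n_genes=12, n_tumor=30, n_normal=30
        )
        t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
        fast = best_combination(t, n, SampleMask.full(30), SearchConfig(h=3))
        naive = naive_best_combination(tumor, normal, np.zeros(30, bool), 3, 0.1)
        _assert_same_combination(fast, naive)

    def test_validation(self):
        tumor = np.ones((2, 2), dtype=np.uint8)
        t, n = pack_instance(tumor, tumor, ["a", "b"], ["x", "y"], ["x", "y"])
        with pytest.raises(ValidationError, match="at least h"):
            best_combination(t, n, SampleMask.full(2), SearchConfig(h=3))
        empty = SampleMask(2, np.zeros(1, dtype=np.uint64))
        with pytest.raises(ValidationError, match="empty mask"):
            best_combination(t, n, empty, SearchConfig(h=2))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(h=st.integers(1, 3), seed=st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_property(self, h, seed):
        rng = np.random.default_rng(seed)
        tumor, normal, genes, t_ids, n_ids = random_instance(rng, n_genes=int(rng.integers(max(3, h), 12)))
        t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
        mask = SampleMask.full(tumor.shape[1])
        fast = best_combination(t, n, mask, SearchConfig(h=h))
        naive = naive_best_combination(
            tumor, normal, np.zeros(tumor.shape[1], bool), h, 0.1
        )
        _assert_same_combination(fast, naive)


class TestGreedyCover:
    def test_forced_two_combination_cover(self):
        tumor = np.zeros((4, 2), dtype=np.uint8)
        tumor[[0, 1], 0] = 1
        tumor[[2, 3], 1] = 1
        normal = np.zeros((4, 4), dtype=np.uint8)
        t, n = pack_instance(tumor, normal, list("abcd"), ["A", "B"], [f"N{j}" for j in range(4)])
        result = greedy_cover(t, n, SearchConfig(h=2))
        assert {c.gene_indices for c in result.combinations} == {(0, 1), (2, 3)}
        assert result.uncovered_tumor_sample_ids == ()
        assert result.iterations == 2

    def test_uncoverable_sample_reported(self):
        # sample B has a single mutated gene: no 2-hit combination covers it
        tumor = np.zeros((3, 2), dtype=np.uint8)
        tumor[[0, 1], 0] = 1
        tumor[2, 1] = 1
        normal = np.zeros((3, 3), dtype=np.uint8)
        t, n = pack_instance(tumor, normal, list("abc"), ["A", "B"], [f"N{j}" for j in range(3)])
        result = greedy_cover(t, n, SearchConfig(h=2))
        assert result.uncovered_tumor_sample_ids == ("B",)
        assert all(c.tp >= 1 for c in result.combinations)

    def test_random_instance_matches_oracle_sequence(self):
        rng = np.random.default_rng(77)
        tumor, normal, genes, t_ids, n_ids = random_instance(
            rng, n_genes=15, n_tumor=40, n_normal=40
        )
        t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
        fast = greedy_cover(t, n, SearchConfig(h=2))
        naive = naive_greedy_cover(tumor, normal, 2, 0.1, genes, t_ids)
        _assert_same_cover(fast, naive)

    def test_denominators_stay_at_initial_totals(self):
        """F recorded in later iterations still divides by the initial
        N_t + N_n, with TP counted over remaining samples only."""
        rng = np.random.default_rng(5)
        tumor, normal, genes, t_ids, n_ids = random_instance(rng, n_genes=8, n_tumor=30, n_normal=20)
        t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
        result = greedy_cover(t, n, SearchConfig(h=2))
        assert len(result.combinations) >= 2
        for combo in result.combinations:
            assert combo.f == pytest.approx((0.1 * combo.tp + combo.tn) / 50, abs=0)

    def test_max_iterations_cap(self):
        rng = np.random.default_rng(6)
        tumor, normal, genes, t_ids, n_ids = random_instance(rng, n_genes=10, n_tumor=40)
        t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
        result = greedy_cover(t, n, SearchConfig(h=2, max_iterations=1))
        assert result.iterations == 1

    def test_empty_tumor_matrix_rejected(self):
        normal = np.zeros((2, 3), dtype=np.uint8)
        t, n = pack_instance(
            np.zeros((2, 0), dtype=np.uint8), normal, ["a", "b"], [], [f"N{j}" for j in range(3)]
        )
        with pytest.raises(ValidationError):
            greedy_cover(t, n, SearchConfig(h=2))


class TestPruning:
    @pytest.mark.parametrize("h", [2, 3])
    def test_prune_never_changes_output(self, h):
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            tumor, normal, genes, t_ids, n_ids = random_instance(rng, n_genes=10)
            t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
            on = greedy_cover(t, n, SearchConfig(h=h, prune=True))
            off = greedy_cover(t, n, SearchConfig(h=h, prune=False))
            _assert_same_cover(on, off)


class TestClassifySample:
    def test_full_containment_is_positive(self):
        assert classify_sample({"A", "B", "C"}, [("A", "B")]) is True

    def test_partial_hit_is_negative(self):
        assert classify_sample({"A"}, [("A", "B")]) is False

    def test_requires_combinations(self):
        with pytest.raises(ValidationError):
            classify_sample({"A"}, [])

    def test_matches_dense_recomputation(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(20)]
        combos = [("g1", "g4", "g7"), ("g0", "g2", "g19")]
        dense = (rng.random((20, 100)) < 0.25).astype(np.uint8)
        for j in range(100):
            sample_genes = {genes[g] for g in np.flatnonzero(dense[:, j])}
            expected = any(
                all(dense[genes.index(g), j] for g in combo) for combo in combos
            )
            assert classify_sample(sample_genes, combos) == expected


class TestReportAndUniverse:
    def test_cover_result_to_report_fields(self):
        rng = np.random.default_rng(21)
        tumor, normal, genes, t_ids, n_ids = random_instance(rng, n_genes=10, n_tumor=30)
        t, n = pack_instance(tumor, normal, genes, t_ids, n_ids)
        result = greedy_cover(t, n, SearchConfig(h=2))
        report = cover_result_to_report(result)
        assert [r.iteration for r in report] == list(range(1, len(report) + 1))
        for row, combo in zip(report, result.combinations):
            assert row.newly_covered == combo.tp >= 1
            assert row.gene_ids == tuple(genes[g] for g in combo.gene_indices)
            assert list(row.gene_ids) == sorted(row.gene_ids, key=genes.index)

    def test_filter_gene_universe(self):
        tumor = np.array([[1, 0], [0, 0], [0, 0]], dtype=np.uint8)
        normal = np.array([[0, 0], [1, 0], [0, 0]], dtype=np.uint8)
        ft, fn, genes = filter_gene_universe(tumor, normal, ["a", "b", "c"])
        assert genes == ["a", "b"]
        ft, fn, genes = filter_gene_universe(tumor, normal, ["a", "b", "c"], tumor_only=True)
        assert genes == ["a"]
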