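"""Friedman, Wilcoxon, Holm, and Bayesian signed-rank comparison suite."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from evomi.stats import (
    barycentric_coordinates,
    bayesian_signed_rank,
    compare_methods,
    friedman_test,
    holm_adjust,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all sign assignments (n <= 10)."""
    d = np.asarray(b, float) - np.asarray(a, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        values = np.tile([[0.5, 0.5, 0.5]], (6, 1))
        statistic, p = friedman_test(values)
        assert statistic == 0.0
        assert p == 1.0

    def test_matches_scipy_without_ties(self, rng):
        values = rng.normal(size=(8, 4))
        statistic, p = friedman_test(values)
        ref_stat, ref_p = sps.friedmanchisquare(*values.T)
        assert statistic == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)

    def test_strict_ordering_matches_rank_formula(self):
        # every observation ranks the 3 algorithms identically
        values = np.array([[0.1, 0.2, 0.3]] * 5)
        statistic, p = friedman_test(values)
        n, k = 5, 3
        rank_sums = np.array([1, 2, 3]) * n
        expected = 12 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)
        assert statistic == pytest.approx(expected)
        assert p < 0.05

    def test_invariant_to_row_wise_constant_shift(self, rng):
        values = rng.normal(size=(6, 3))
        shifted = values.copy()
        shifted[2] += 100.0
        assert friedman_test(values)[0] == pytest.approx(friedman_test(shifted)[0])

    def test_too_small_matrix_raises(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        a = np.zeros(5)
        b = np.arange(1.0, 6.0)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(2 / 32)

    def test_equal_series_give_one(self):
        a = np.arange(6.0)
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_antisymmetric_differences_statistic_at_mean(self):
        # +d/-d pairs put W+ exactly at its null mean -> p near 1
        a = np.zeros(6)
        b = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert wilcoxon_signed_rank(a, b) > 0.8

    def test_exact_branch_matches_full_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 11))
            a = rng.normal(size=n)
            b = a + rng.normal(size=n)
            # re-draw ties away (continuous data almost surely tie-free)
            p = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(a, b))

    def test_exact_branch_with_tied_ranks_matches_enumeration(self):
        a = np.zeros(6)
        b = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_enumeration_oracle(a, b)
        )

    def test_normal_approximation_close_to_scipy(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.3, 1.0, size=40)
        p = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(b, a, correction=True, method="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(5), np.zeros(6))


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.04]), [0.04])

    def test_hand_worked_step_down(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 8)))
            ref = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)

    def test_outputs_dominate_inputs_and_capped(self, rng):
        p = rng.random(10)
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_order_invariance(self, rng):
        p = rng.random(6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(holm_adjust(p)[perm], holm_adjust(p[perm]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


def dirichlet_max_prob_oracle(alpha, n_grid=400):
    """P(coordinate i is the largest) for Dirichlet(alpha) by quadrature."""
    # integrate the density over the simplex on a regular grid
    xs = (np.arange(n_grid) + 0.5) / n_grid
    probs = np.zeros(3)
    total = 0.0
    from scipy.special import gammaln

    log_norm = gammaln(np.sum(alpha)) - np.sum(gammaln(alpha))
    for i, x in enumerate(xs):
        for y in xs:
            z = 1.0 - x - y
            if z <= 0:
                continue
            log_d = (
                log_norm
                + (alpha[0] - 1) * np.log(x)
                + (alpha[1] - 1) * np.log(y)
                + (alpha[2] - 1) * np.log(z)
            )
            w = np.exp(log_d)
            total += w
            probs[int(np.argmax([x, y, z]))] += w
    return probs / total


class TestBayesianSignedRank:
    def test_probabilities_sum_to_one_and_triplets_on_simplex(self, rng):
        a = rng.normal(size=20)
        b = a + rng.normal(0.1, 0.2, size=20)
        res = bayesian_signed_rank(a, b, rng=rng)
        assert res.p_left + res.p_rope + res.p_right == pytest.approx(1.0)
        assert res.sampled_triplets.shape == (2000, 3)
        np.testing.assert_allclose(res.sampled_triplets.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.sampled_triplets >= 0)

    def test_dominant_right_when_b_always_better(self, rng):
        a = np.zeros(30)
        b = np.full(30, 0.5)
        res = bayesian_signed_rank(a, b, rng=rng)
        assert res.p_right > 0.95

    def test_rope_dominant_for_identical_series(self, rng):
        a = np.full(15, 0.6)
        res = bayesian_signed_rank(a, a.copy(), rng=rng)
        assert res.p_rope > 0.9
        assert res.counts == (0, 15, 0)

    def test_matches_quadrature_oracle_on_fixed_counts(self):
        # counts (2, 5, 13) with prior pseudocount 1 in the rope ->
        # Dirichlet(2, 6, 13)
        rng = np.random.default_rng(0)
        a = np.zeros(20)
        b = np.concatenate([-np.ones(2), np.zeros(5), np.ones(13)]) * 0.5
        res = bayesian_signed_rank(a, b, n_samples=100_000, rng=rng)
        assert res.counts == (2, 5, 13)
        oracle = dirichlet_max_prob_oracle(np.array([2.0, 6.0, 13.0]))
        mc_tol = 3.5 / np.sqrt(100_000) + 0.003  # MC error + grid error
        assert res.p_left == pytest.approx(oracle[0], abs=mc_tol)
        assert res.p_rope == pytest.approx(oracle[1], abs=mc_tol)
        assert res.p_right == pytest.approx(oracle[2], abs=mc_tol)

    def test_swapping_series_mirrors_probabilities(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = a + rng.normal(0.2, 0.5, size=40)
        r1 = bayesian_signed_rank(a, b, n_samples=50_000, rng=np.random.default_rng(1))
        r2 = bayesian_signed_rank(b, a, n_samples=50_000, rng=np.random.default_rng(1))
        assert r1.counts == r2.counts[::-1]
        assert r1.p_left == pytest.approx(r2.p_right, abs=0.02)
        assert r1.p_rope == pytest.approx(r2.p_rope, abs=0.02)

    def test_empty_series_raises(self, rng):
        with pytest.raises(ValueError):
            bayesian_signed_rank([], [], rng=rng)


class TestBarycentric:
    def test_pure_triplets_hit_vertices(self):
        left = barycentric_coordinates([1.0, 0.0, 0.0])
        right = barycentric_coordinates([0.0, 0.0, 1.0])
        top = barycentric_coordinates([0.0, 1.0, 0.0])
        np.testing.assert_allclose(left, [0.0, 0.0])
        np.testing.assert_allclose(right, [1.0, 0.0])
        np.testing.assert_allclose(top, [0.5, np.sqrt(3) / 2])

    def test_uniform_triplet_hits_centroid(self):
        centroid = barycentric_coordinates([1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(centroid, [0.5, np.sqrt(3) / 6], atol=1e-12)

    def test_map_is_affine(self, rng):
        t1 = rng.dirichlet([1, 1, 1])
        t2 = rng.dirichlet([1, 1, 1])
        mid = (t1 + t2) / 2
        np.testing.assert_allclose(
            barycentric_coordinates(mid),
            (barycentric_coordinates(t1) + barycentric_coordinates(t2)) / 2,
        )

    def test_off_simplex_raises(self):
        with pytest.raises(ValueError):
            barycentric_coordinates([0.5, 0.5, 0.5])


class TestCompareMethods:
    def test_identical_methods_gate_posthoc(self, rng):
        values = np.tile(rng.random(10)[:, None], (1, 3))
        report = compare_methods(values, ["a", "b", "c"], rng=rng)
        assert report.friedman_p == 1.0
        assert not report.posthoc_run
        assert report.pairwise_p_holm == {}

    def test_dominant_method_flagged_by_bayes(self, rng):
        n = 20
        base = rng.random(n) * 0.1 + 0.5
        values = np.column_stack([base, base + 0.05, base + 0.30])
        report = compare_methods(values, ["m0", "m1", "m2"], rng=rng)
        assert report.posthoc_run
        assert report.bayesian[("m0", "m2")].p_right > 0.9

    def test_pairwise_count_is_k_choose_2(self, rng):
        values = rng.random((12, 4)) + np.array([0.0, 0.2, 0.4, 0.6])
        report = compare_methods(values, rng=rng)
        assert len(report.pairwise_p_holm) == 6
        assert "Friedman" in report.to_text()
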