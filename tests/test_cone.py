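"""Cone projection, chi-bar weights, and the two Wald-type tests."""

import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.stats import chi2

from epijack.core import (
    Cov4,
    LocalOdds,
    chibar_tail_mc,
    chibar_weights,
    naive_dosage_test,
    project_to_cone,
    wtt,
    wtt_c,
)
from epijack.core import PosteriorMatrix, build_count_table, analytic_variance, estimate_beta

from conftest import random_pd_cov

I4 = Cov4(V=np.eye(4), provenance="analytic")


def nnls_cone_projection(beta: np.ndarray, V: np.ndarray) -> float:
    """Independent iterative oracle for the union-cone squared distance.

    Projection onto the nonnegative orthant in the V^{-1} metric is the
    non-negative least squares problem min ||L^T x - L^T beta||^2 with
    L L^T = V^{-1}; the nonpositive orthant is the same problem at -beta.
    """
    W = np.linalg.inv(V)
    L = np.linalg.cholesky(0.5 * (W + W.T))
    A = L.T
    dists = []
    for sign in (+1, -1):
        _, resid = nnls(A, A @ (sign * beta))
        dists.append(resid**2)
    return min(dists)


class TestProjection:
    def test_interior_point_unchanged(self):
        b = LocalOdds(np.ones(4))
        star, qdist, dim = project_to_cone(b, I4)
        np.testing.assert_array_equal(star.beta, b.beta)
        assert qdist == 0.0 and dim == 4

    def test_mixed_signs_tie_breaks_to_nonneg(self):
        star, qdist, dim = project_to_cone(LocalOdds(np.array([1.0, -1, 0, 0])), I4)
        np.testing.assert_allclose(star.beta, [1, 0, 0, 0])
        assert qdist == pytest.approx(1.0)
        assert dim == 1

    def test_nonpositive_interior(self, rng):
        b = np.array([-2.0, -1.0, -3.0, -0.5])
        star, qdist, dim = project_to_cone(LocalOdds(b), random_pd_cov(rng))
        np.testing.assert_allclose(star.beta, b)
        assert qdist == pytest.approx(0.0, abs=1e-10)
        assert dim == 4

    def test_face_enumeration_matches_nnls_oracle(self, rng):
        # exhaustive-face QP vs an independent iterative solver
        for _ in range(1000):
            V = random_pd_cov(rng)
            b = LocalOdds(rng.standard_normal(4) * rng.uniform(0.2, 3))
            _, qdist, _ = project_to_cone(b, V)
            assert qdist == pytest.approx(
                nnls_cone_projection(b.beta, V.V), abs=1e-8
            )


class TestChiBarWeights:
    def test_single_orthant_binomial_weights(self):
        w = chibar_weights(I4, mc_draws=100_000, seed=3, cone="nonneg").w
        target = np.array([1, 4, 6, 4, 1]) / 16
        se = np.sqrt(target * (1 - target) / 100_000)
        assert np.all(np.abs(w - target) <= 3 * se)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        V = random_pd_cov(rng)
        w1 = chibar_weights(V, mc_draws=5000, seed=7).w
        w2 = chibar_weights(
            Cov4(V=17.0 * V.V, provenance="analytic"), mc_draws=5000, seed=7
        ).w
        np.testing.assert_array_equal(w1, w2)

    def test_deterministic_given_seed(self, rng):
        V = random_pd_cov(rng)
        w1 = chibar_weights(V, mc_draws=5000, seed=11).w
        w2 = chibar_weights(V, mc_draws=5000, seed=11).w
        np.testing.assert_array_equal(w1, w2)

    def test_winning_method_sums_to_one(self, rng):
        w = chibar_weights(random_pd_cov(rng), mc_draws=5000, seed=2,
                           method="winning").w
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mixture_tail_matches_direct_mc(self, rng):
        # The two-sided mixture is a union bound on the null tail: never below
        # the truth (beyond MC error) at any threshold, so p-values are valid.
        for V in (I4, random_pd_cov(rng)):
            w = chibar_weights(V, mc_draws=100_000, seed=5)
            ts = np.array([1.0, 2.7, 5.0, 9.0])
            emp = chibar_tail_mc(V, ts, mc_draws=100_000, seed=6)
            for t, e in zip(ts, emp):
                se = np.sqrt(max(e * (1 - e), 1e-12) / 100_000)
                assert w.tail(t) >= e - 3 * se

    def test_mixture_calibrated_at_conventional_levels(self, rng):
        # at the mixture's own 5% and 1% critical values the true rejection
        # probability is within 10% relative of nominal
        from scipy.optimize import brentq

        for V in (I4, random_pd_cov(rng), random_pd_cov(rng)):
            w = chibar_weights(V, mc_draws=100_000, seed=5)
            for level in (0.05, 0.01):
                crit = brentq(lambda t: w.tail(t) - level, 0.5, 60)
                true_tail = chibar_tail_mc(V, [crit], mc_draws=200_000, seed=6)[0]
                se = np.sqrt(level * (1 - level) / 200_000)
                assert abs(true_tail - level) <= 0.10 * level + 3 * se


class TestWTT:
    def test_zero_beta(self):
        res = wtt(LocalOdds(np.zeros(4)), I4)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_identity_variance_tail(self):
        res = wtt(LocalOdds(np.ones(4)), I4)
        assert res.statistic == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(chi2.sf(4.0, 4))
        assert res.pvalue == pytest.approx(0.4060, abs=5e-4)

    def test_singular_variance_rejected(self):
        V = Cov4(V=np.diag([1.0, 1.0, 1.0, 0.0]), provenance="analytic")
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            wtt(LocalOdds(np.ones(4)), V)

    def test_allele_relabel_invariance(self, rng):
        # flipping allele coding at G reverses the genotype index l -> 2-l
        for _ in range(20):
            g = rng.integers(0, 3, 200)
            h = rng.integers(0, 3, 200)
            t1 = build_count_table(g, h)
            t2 = build_count_table(2 - g, h)
            try:
                r1 = wtt(estimate_beta(t1), analytic_variance(t1))
                r2 = wtt(estimate_beta(t2), analytic_variance(t2))
            except ValueError:
                continue  # zero cell in this draw
            assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)


class TestWTTc:
    def test_equals_wtt_inside_cone(self, rng):
        V = random_pd_cov(rng)
        b = LocalOdds(np.abs(rng.standard_normal(4)))
        w = chibar_weights(V, mc_draws=2000, seed=1)
        assert wtt_c(b, V, weights=w).statistic == pytest.approx(
            wtt(b, V).statistic
        )

    def test_statistic_subtracts_cone_distance(self):
        w = chibar_weights(I4, mc_draws=2000, seed=1)
        res = wtt_c(LocalOdds(np.array([1.0, -1, 0, 0])), I4, weights=w)
        assert res.statistic == pytest.approx(1.0)  # 2 - 1

    def test_zero_beta(self):
        w = chibar_weights(I4, mc_draws=2000, seed=1)
        res = wtt_c(LocalOdds(np.zeros(4)), I4, weights=w)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_never_exceeds_wtt(self, rng):
        w_cache = {}
        for _ in range(200):
            V = random_pd_cov(rng)
            b = LocalOdds(rng.standard_normal(4) * 2)
            w = chibar_weights(V, mc_draws=1000, seed=0)
            c = wtt_c(b, V, weights=w).statistic
            u = wtt(b, V).statistic
            assert 0.0 <= c <= u + 1e-9

    def test_relabel_invariance_constrained(self, rng):
        for _ in range(10):
            g = rng.integers(0, 3, 500)
            h = rng.integers(0, 3, 500)
            t1 = build_count_table(g, h)
            t2 = build_count_table(g, 2 - h)
            try:
                V1, V2 = analytic_variance(t1), analytic_variance(t2)
            except ValueError:
                continue
            w1 = chibar_weights(V1, mc_draws=2000, seed=4)
            w2 = chibar_weights(V2, mc_draws=2000, seed=4)
            s1 = wtt_c(estimate_beta(t1), V1, weights=w1).statistic
            s2 = wtt_c(estimate_beta(t2), V2, weights=w2).statistic
            assert s1 == pytest.approx(s2, rel=1e-8, abs=1e-10)


class TestNaiveDosage:
    def test_degenerate_posteriors_match_truth_test(self, rng):
        g = rng.integers(0, 3, 900)
        h = rng.integers(0, 3, 900)
        post = PosteriorMatrix.from_calls(g, h)
        tab = build_count_table(g, h)
        truth = wtt(estimate_beta(tab), analytic_variance(tab))
        naive = naive_dosage_test(post, constrained=False)
        assert naive.statistic == pytest.approx(truth.statistic, rel=1e-10)
        assert naive.method == "naive_dosage_WTT"
        assert naive.variance_provenance == "naive_dosage"

    def test_finite_nonnegative(self, rng):
        pG = rng.dirichlet(np.full(3, 2.0), size=300)
        pH = rng.dirichlet(np.full(3, 2.0), size=300)
        res = naive_dosage_test(PosteriorMatrix(pG=pG, pH=pH), constrained=True,
                                mc_draws=1000, seed=0)
        assert np.isfinite(res.statistic) and res.statistic >= 0
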