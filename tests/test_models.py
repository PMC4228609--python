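"""Covariance builders, MVN likelihood, and maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from scipy import linalg

import litterevo as le
from litterevo.models import SingularCovarianceError, _gls_profile
from litterevo.simulate import SimulationConfig, simulate_traits, simulate_tree

from conftest import random_tree


def mvn_logpdf_oracle(x, mean, V):
    """Dense inverse/determinant MVN log-density, independent of the package."""
    n = len(x)
    resid = np.asarray(x) - mean
    return float(
        -0.5
        * (
            n * math.log(2 * math.pi)
            + math.log(np.linalg.det(V))
            + resid @ np.linalg.inv(V) @ resid
        )
    )


class TestCovarianceBuilders:
    def test_bm_direct_product(self, three_tip_tree):
        sam = le.shared_ancestry(three_tip_tree, ["A", "B", "C"])
        V = le.bm_covariance(sam, beta=1.0)
        np.testing.assert_allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])
        np.testing.assert_allclose(le.bm_covariance(sam, 2.0), 2 * V)

    def test_bm_rejects_nonpositive_rate(self, three_tip_tree):
        sam = le.shared_ancestry(three_tip_tree)
        with pytest.raises(ValueError):
            le.bm_covariance(sam, 0.0)

    def test_eb_r_zero_is_bm(self, study_tree):
        sam = le.shared_ancestry(study_tree)
        np.testing.assert_allclose(
            le.eb_covariance(sam, 0.5, 0.0), le.bm_covariance(sam, 0.5)
        )

    def test_eb_two_tip_closed_form(self):
        # depth-T cherry with r = -ln2/T: variance = beta*T/(2 ln 2)
        T = 10.0
        tree = le.parse_newick(f"(A:{T},B:{T});")
        sam = le.shared_ancestry(tree, ["A", "B"])
        r = -math.log(2) / T
        V = le.eb_covariance(sam, beta=3.0, r=r)
        assert V[0, 0] == pytest.approx(3.0 * T / (2 * math.log(2)))
        # cross-check against numerical integration of beta*exp(r s) over [0,T]
        s = np.linspace(0, T, 20001)
        assert V[0, 0] == pytest.approx(np.trapezoid(3.0 * np.exp(r * s), s), rel=1e-6)

    def test_eb_entries_shrink_with_stronger_deceleration(self, study_tree):
        sam = le.shared_ancestry(study_tree)
        prev = le.eb_covariance(sam, 1.0, 0.0)
        for r in (-0.01, -0.1):
            cur = le.eb_covariance(sam, 1.0, r)
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_eb_rejects_accelerating(self, study_tree):
        sam = le.shared_ancestry(study_tree)
        with pytest.raises(ValueError):
            le.eb_covariance(sam, 1.0, 0.1)

    def test_ou_small_alpha_is_bm_limit(self, study_tree):
        sam = le.shared_ancestry(study_tree)
        beta = 0.7
        V = le.ou_covariance(sam, beta, 1e-10)
        dev = np.abs(V - le.bm_covariance(sam, beta)).max()
        assert dev < 1e-6 * beta * sam.depth

    def test_ou_ultrametric_diagonal(self, study_tree):
        sam = le.shared_ancestry(study_tree)
        beta, alpha = 0.012, 0.036
        V = le.ou_covariance(sam, beta, alpha)
        T = sam.depth
        expected = beta / (2 * alpha) * (1 - math.exp(-2 * alpha * T))
        np.testing.assert_allclose(np.diag(V), expected, rtol=1e-9)

    def test_ou_two_tip_matches_simulation_oracle(self):
        """Simulate the OU process along the tree (exact AR(1) transitions
        over the shared stem, then two independent branches) and compare the
        empirical tip covariance with the closed form."""
        s, t = 3.0, 5.0  # MRCA depth and tip depth
        tree = le.parse_newick(f"((A:{t - s},B:{t - s}):{s});")
        sam = le.shared_ancestry(tree, ["A", "B"])
        beta, alpha = 0.8, 0.4
        V = le.ou_covariance(sam, beta, alpha)

        rng = np.random.default_rng(99)
        reps = 300_000
        stat = beta / (2 * alpha)

        def ou_step(x, dt):
            decay = math.exp(-alpha * dt)
            sd = math.sqrt(stat * (1 - decay**2))
            return x * decay + rng.standard_normal(reps) * sd

        x_mrca = ou_step(np.zeros(reps), s)
        xa, xb = ou_step(x_mrca, t - s), ou_step(x_mrca, t - s)
        emp_cov = np.cov(xa, xb)
        mc_se = stat / math.sqrt(reps) * 3  # generous 3-SE band
        assert abs(emp_cov[0, 1] - V[0, 1]) < 3 * mc_se + 3e-3
        assert abs(emp_cov[0, 0] - V[0, 0]) < 3 * mc_se + 3e-3

    def test_all_builders_symmetric_near_psd(self, study_tree):
        sam = le.shared_ancestry(study_tree)
        for V in (
            le.bm_covariance(sam, 0.012),
            le.eb_covariance(sam, 0.012, -0.01),
            le.ou_covariance(sam, 0.012, 0.036),
        ):
            np.testing.assert_allclose(V, V.T)
            assert np.linalg.eigvalsh(V).min() >= -1e-9 * np.trace(V)


class TestLogLikelihood:
    def test_univariate_normal(self):
        tv = le.TraitVector(["A"], np.array([1.3]))
        v, z0 = 0.7, 0.5
        expected = -0.5 * (math.log(2 * math.pi * v) + (1.3 - z0) ** 2 / v)
        assert le.log_likelihood(np.array([[v]]), z0, tv) == pytest.approx(expected)

    def test_zero_se_identical_to_no_se(self, three_tip_tree):
        sam = le.shared_ancestry(three_tip_tree, ["A", "B", "C"])
        V = le.bm_covariance(sam, 0.5)
        x = np.array([0.1, -0.2, 0.4])
        a = le.TraitVector(["A", "B", "C"], x, se=np.zeros(3))
        b = le.TraitVector(["A", "B", "C"], x)
        assert le.log_likelihood(V, 0.0, a, use_se=True) == pytest.approx(
            le.log_likelihood(V, 0.0, b, use_se=False)
        )

    def test_matches_dense_oracle(self, three_tip_tree):
        sam = le.shared_ancestry(three_tip_tree, ["A", "B", "C"])
        V = le.ou_covariance(sam, 0.9, 0.3)
        x = np.array([0.4, -0.1, 0.6])
        se = np.array([0.05, 0.1, 0.0])
        tv = le.TraitVector(["A", "B", "C"], x, se=se)
        got = le.log_likelihood(V, 0.2, tv, use_se=True)
        assert got == pytest.approx(
            mvn_logpdf_oracle(x, 0.2, V + np.diag(se**2)), abs=1e-8
        )

    def test_singular_covariance_reports_condition(self):
        tv = le.TraitVector(["A", "B"], np.array([0.0, 0.0]))
        V = np.array([[1.0, 1.0], [1.0, 1.0]])  # duplicated tips
        with pytest.raises(SingularCovarianceError):
            le.log_likelihood(V, 0.0, tv)


class TestFitML:
    def test_bm_matches_closed_form_gls(self, study_tree, rng):
        vals, order = simulate_traits(study_tree, "BM", 0.012, -6.0, seed=5)
        tv = le.TraitVector(order, vals[0])
        fit = le.fit_ml("BM", tv, study_tree, le.FitOptions(seed=1))
        C = le.shared_ancestry(study_tree).reorder(order).t_shared
        z0, Q, _ = _gls_profile(C, vals[0])
        assert fit.z0 == pytest.approx(z0, rel=1e-6)
        assert fit.beta == pytest.approx(Q / len(order), rel=1e-6)

    def test_nested_models_reach_bm_likelihood(self, study_tree):
        vals, order = simulate_traits(study_tree, "BM", 0.012, 0.0, seed=6)
        tv = le.TraitVector(order, vals[0])
        opts = le.FitOptions(seed=1)
        bm = le.fit_ml("BM", tv, study_tree, opts)
        eb = le.fit_ml("EB", tv, study_tree, opts)
        ou = le.fit_ml("OU", tv, study_tree, opts)
        assert eb.lnL >= bm.lnL - 1e-6
        assert ou.lnL >= bm.lnL - 1e-6

    def test_eb_forced_to_zero_reproduces_bm(self, study_tree):
        vals, order = simulate_traits(study_tree, "BM", 0.012, 0.0, seed=7)
        tv = le.TraitVector(order, vals[0])
        bm = le.fit_ml("BM", tv, study_tree, le.FitOptions(seed=1))
        eb = le.fit_ml(
            "EB", tv, study_tree, le.FitOptions(seed=1, r_bounds=(0.0, 0.0))
        )
        assert eb.lnL == pytest.approx(bm.lnL, abs=1e-9)
        assert eb.beta == pytest.approx(bm.beta, rel=1e-9)

    def test_permutation_invariance(self, study_tree):
        vals, order = simulate_traits(study_tree, "OU", 0.012, 0.0, seed=8,
                                      alpha=0.036)
        tv = le.TraitVector(order, vals[0])
        perm = list(reversed(range(len(order))))
        tv_p = le.TraitVector([order[i] for i in perm], vals[0][perm])
        f1 = le.fit_ml("OU", tv, study_tree, le.FitOptions(seed=1))
        f2 = le.fit_ml("OU", tv_p, study_tree, le.FitOptions(seed=1))
        assert f2.lnL == pytest.approx(f1.lnL, abs=1e-8)
        assert f2.alpha == pytest.approx(f1.alpha, rel=1e-6)

    def test_missing_species_listed(self, three_tip_tree):
        tv = le.TraitVector(["A", "B", "Z"], np.zeros(3))
        with pytest.raises(ValueError, match="Z"):
            le.fit_ml("BM", tv, three_tip_tree)

    def test_measurement_error_shrinks_rate(self, study_tree):
        """Inflating the diagonal with known error absorbs variance that the
        no-error fit would attribute to evolution."""
        vals, order = simulate_traits(study_tree, "BM", 0.012, 0.0, seed=9)
        noisy = vals[0] + np.random.default_rng(3).normal(0, 0.5, len(order))
        se = np.full(len(order), 0.5)
        tv = le.TraitVector(order, noisy, se=se)
        with_se = le.fit_ml("BM", tv, study_tree, le.FitOptions(seed=1, use_se=True))
        without = le.fit_ml("BM", tv, study_tree, le.FitOptions(seed=1))
        assert with_se.beta < without.beta
        assert with_se.lnL >= without.lnL  # extra diagonal variance fits noise

    def test_fit_reports_information_scores(self, study_tree):
        vals, order = simulate_traits(study_tree, "OU", 0.012, 0.0, seed=10,
                                      alpha=0.036)
        tv = le.TraitVector(order, vals[0])
        fit = le.fit_ml("OU", tv, study_tree, le.FitOptions(seed=1))
        n, p = fit.n, fit.p
        assert p == 3 and n == 39
        assert fit.aic == pytest.approx(-2 * fit.lnL + 2 * p)
        assert fit.aicc == pytest.approx(fit.aic + 2 * p * (p + 1) / (n - p - 1))
        assert fit.aicc >= fit.aic
        assert fit.half_life == pytest.approx(math.log(2) / fit.alpha)

    def test_free_optimum_convention_counts_four(self, study_tree):
        vals, order = simulate_traits(study_tree, "OU", 0.012, 0.0, seed=10,
                                      alpha=0.036)
        tv = le.TraitVector(order, vals[0])
        fit = le.fit_ml(
            "OU", tv, study_tree, le.FitOptions(seed=1, free_optimum_params=True)
        )
        assert fit.p == 4


class TestHalfLife:
    def test_definition(self):
        assert le.phylogenetic_half_life(math.log(2)) == pytest.approx(1.0)

    def test_bm_limit_is_infinite(self):
        assert le.phylogenetic_half_life(0.0) == math.inf
        assert le.phylogenetic_half_life(-1.0) == math.inf
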