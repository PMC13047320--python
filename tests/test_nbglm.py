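"""NB GLM engine: size factors, dispersion, fits, Wald, shrinkage, BH."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from skinsynergy import nbglm


class TestSizeFactors:
    def test_exact_scaling(self):
        a = np.array([[10.0, 20.0], [5.0, 10.0], [100.0, 200.0]])
        sf = nbglm.size_factors(a)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_identical_columns_equal_factors(self):
        a = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 5))
        sf = nbglm.size_factors(a)
        np.testing.assert_allclose(sf, sf[0])

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 500, size=(200, 6)).astype(float)
        sf = nbglm.size_factors(counts)
        # independent re-implementation
        loggeo = np.log(counts).mean(axis=1)
        expected = [
            np.exp(np.median(np.log(counts[:, j]) - loggeo))
            for j in range(6)
        ]
        np.testing.assert_allclose(sf, expected, atol=1e-12)

    def test_no_allpositive_gene_suggests_poscounts(self):
        counts = np.array([[0.0, 5.0], [5.0, 0.0]])
        with pytest.raises(ValueError, match="poscounts"):
            nbglm.size_factors(counts)
        sf = nbglm.size_factors(counts, method="poscounts")
        assert np.all(sf > 0)


class TestDispersion:
    def test_poisson_genes_estimated_near_zero(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(100.0, size=(100, 50))
        d = nbglm.two_group_design(np.r_[np.zeros(25), np.ones(25)])
        alpha, _ = nbglm.estimate_dispersion(y, d, np.ones(50))
        assert alpha.max() < 0.05

    def test_parameter_recovery_alpha_half(self):
        rng = np.random.default_rng(3)
        r = 1.0 / 0.5
        y = rng.negative_binomial(r, r / (r + 100.0), size=(200, 200))
        d = nbglm.two_group_design(np.r_[np.zeros(100), np.ones(100)])
        alpha, _ = nbglm.estimate_dispersion(y, d, np.ones(200))
        inside = ((alpha >= 0.35) & (alpha <= 0.65)).mean()
        assert inside >= 0.90

    def test_constant_counts_hit_floor(self):
        y = np.full((12, 6), 50.0)
        d = nbglm.two_group_design(np.r_[np.zeros(3), np.ones(3)])
        alpha, _ = nbglm.estimate_dispersion(y, d, np.ones(6), moderate=False)
        assert np.all(alpha <= 1e-6)


class TestFitGlm:
    def test_poisson_two_group_closed_form(self):
        rng = np.random.default_rng(1)
        y = np.vstack(
            [rng.poisson([100] * 3 + [300] * 3) for _ in range(10)]
        ).astype(float)
        d = nbglm.two_group_design(np.r_[np.zeros(3), np.ones(3)])
        beta, _, _ = nbglm.fit_glm(y, d, np.ones(6), np.zeros(10))
        expected = np.log(y[:, 3:].mean(1) / y[:, :3].mean(1))
        np.testing.assert_allclose(beta[:, 1], expected, atol=1e-8)

    def test_all_zero_gene_flagged_degenerate(self):
        y = np.zeros((1, 6))
        d = nbglm.two_group_design(np.r_[np.zeros(3), np.ones(3)])
        beta, _, degenerate = nbglm.fit_glm(y, d, np.ones(6), np.zeros(1))
        assert degenerate[0]
        np.testing.assert_array_equal(beta[0], 0.0)

    def test_coverage_of_true_coefficient(self):
        # known beta recovered within 3 SE in >= 95% of replicates
        rng = np.random.default_rng(11)
        n_rep, alpha_true, beta_true = 1000, 0.1, np.log(2.0)
        r = 1.0 / alpha_true
        mu = np.tile(np.r_[[100.0] * 3, [100.0 * 2] * 3], (n_rep, 1))
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        d = nbglm.two_group_design(np.r_[np.zeros(3), np.ones(3)])
        beta, cov, _ = nbglm.fit_glm(
            y, d, np.ones(6), np.full(n_rep, alpha_true)
        )
        se = np.sqrt(cov[:, 1, 1])
        covered = np.abs(beta[:, 1] - beta_true) <= 3 * se
        assert covered.mean() >= 0.95

    def test_wald_agrees_with_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        alpha = 0.2
        r = 1.0 / alpha
        d = nbglm.two_group_design(np.r_[np.zeros(5), np.ones(5)])
        mu = np.r_[[200.0] * 5, [500.0] * 5]
        y = rng.negative_binomial(r, r / (r + mu), size=(50, 10)).astype(float)
        beta, cov, _ = nbglm.fit_glm(y, d, np.ones(10), np.full(50, alpha))
        ours = beta[:, 1] / np.sqrt(cov[:, 1, 1])
        for i in range(50):
            fit = sm.GLM(
                y[i], d.matrix,
                family=sm.families.NegativeBinomial(alpha=alpha),
            ).fit()
            theirs = fit.params[1] / fit.bse[1]
            assert ours[i] == pytest.approx(theirs, rel=0.10)


class TestWald:
    def test_critical_value(self):
        p = nbglm.wald_test(np.array([1.959964]), np.array([1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-4)

    def test_zero_effect_p_one(self):
        assert nbglm.wald_test(np.array([0.0]), np.array([1.0]))[0] == 1.0

    def test_zero_se_flagged_nan(self):
        assert np.isnan(nbglm.wald_test(np.array([1.0]), np.array([0.0]))[0])


class TestShrinkage:
    def test_zero_stays_zero(self):
        s, _ = nbglm.shrink_lfc(np.array([0.0]), np.array([1.0]), prior_scale=0.5)
        assert s[0] == 0.0

    def test_precise_estimates_unshrunk(self):
        s, _ = nbglm.shrink_lfc(np.array([2.0]), np.array([1e-4]), prior_scale=0.5)
        assert s[0] == pytest.approx(2.0, abs=1e-3)

    def test_never_flips_sign_and_contracts(self):
        rng = np.random.default_rng(9)
        beta = rng.normal(0, 2, 50)
        se = rng.uniform(0.05, 1.5, 50)
        s, _ = nbglm.shrink_lfc(beta, se, prior_scale=0.3)
        assert np.all(np.abs(s) <= np.abs(beta) + 1e-6)
        assert np.all(s * beta >= -1e-6)

    def test_posterior_mode_matches_brute_force_optimizer(self):
        scale = 0.4
        for b in (-3.0, -0.7, 0.2, 1.5, 4.0):
            for se in (0.1, 0.5, 1.2):
                s, _ = nbglm.shrink_lfc(
                    np.array([b]), np.array([se]), prior_scale=scale
                )
                ref = minimize_scalar(
                    lambda x: (x - b) ** 2 / (2 * se**2)
                    + np.log1p((x / scale) ** 2),
                    bounds=(min(0.0, b), max(0.0, b)),
                    method="bounded",
                    options={"xatol": 1e-10},
                ).x
                assert s[0] == pytest.approx(ref, abs=1e-6)


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            nbglm.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert nbglm.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_nan_excluded_from_m(self):
        adj = nbglm.bh_adjust(np.array([0.01, np.nan, 0.02]))
        np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.02])
        assert np.isnan(adj[1])

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            nbglm.bh_adjust(p), mt.multipletests(p, method="fdr_bh")[1]
        )

    def test_uniform_null_fdr_controlled(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=5000)
        frac = (nbglm.bh_adjust(p) < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert frac <= 0.05 + 3 * se

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40)
    )
    def test_monotone_in_p(self, ps):
        p = np.array(ps)
        adj = nbglm.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
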