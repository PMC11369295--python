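"""Joint copula regression: likelihood oracles, MLE self-consistency,
screen bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import norm

from adipocop.copula import bb1_logdensity, sample_bb1
from adipocop.jointmodel import (
    CopulaJointModel,
    bonferroni_cutoff,
    build_design,
    fit_copula_model,
    joint_loglik,
    linear_screen,
    transcriptome_screen,
)


def _simulate_pair(n, beta1=0.0, beta2=0.0, phi=1.125, theta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), g])
    uv = sample_bb1(n, phi, theta, seed=rng)
    y1 = 3.0 + beta1 * g + ndtri(uv[:, 0]) * 0.35
    y2 = 0.8 + beta2 * g + ndtri(uv[:, 1]) * 0.07
    return y1, y2, X


class TestLoglik:
    def test_independence_decomposition(self):
        """At phi -> 0, theta = 1 the joint log-likelihood is the sum of the
        two Gaussian regression log-likelihoods."""
        rng = np.random.default_rng(1)
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y1 = 3.0 + 0.3 * X[:, 1] + rng.normal(0, 0.35, n)
        y2 = 0.8 + rng.normal(0, 0.07, n)
        params = np.array(
            [3.0, 0.3, np.log(0.35), 0.8, 0.0, np.log(0.07), np.log(1e-8), np.log(1e-8)]
        )
        ll = joint_loglik(y1, y2, X, params)
        ll_ind = (
            norm.logpdf(y1, X @ [3.0, 0.3], 0.35).sum()
            + norm.logpdf(y2, X @ [0.8, 0.0], 0.07).sum()
        )
        assert ll == pytest.approx(ll_ind, abs=1e-4)

    def test_single_observation_composition(self):
        """One observation: the likelihood is the copula log-density at the
        Gaussian PIT points plus the two Gaussian log-pdfs."""
        y1, y2 = np.array([3.2]), np.array([0.75])
        X = np.array([[1.0, 0.5]])
        g1, s1 = np.array([3.0, 0.1]), 0.3
        g2, s2 = np.array([0.8, -0.05]), 0.06
        phi, theta = 1.3, 1.4
        params = np.concatenate(
            [g1, [np.log(s1)], g2, [np.log(s2)], [np.log(phi)], [np.log(theta - 1)]]
        )
        r1 = (y1[0] - X[0] @ g1) / s1
        r2 = (y2[0] - X[0] @ g2) / s2
        expected = (
            bb1_logdensity(norm.cdf(r1), norm.cdf(r2), (phi, theta))
            + norm.logpdf(y1[0], X[0] @ g1, s1)
            + norm.logpdf(y2[0], X[0] @ g2, s2)
        )
        model = CopulaJointModel.__new__(CopulaJointModel)
        model.y1, model.y2, model.exog = y1, y2, X
        model.k_exog, model.nobs = 2, 1
        model.exog_names = ["const", "x"]
        assert model.loglike(params) == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self):
        y1, y2, X = _simulate_pair(200, seed=2)
        params = np.array(
            [3.0, 0.1, np.log(0.35), 0.8, 0.0, np.log(0.07), np.log(1.0), np.log(0.5)]
        )
        base = joint_loglik(y1, y2, X, params)
        shifted = params.copy()
        shifted[0] += 4.0
        assert joint_loglik(y1 + 4.0, y2, X, shifted) == pytest.approx(base, abs=1e-9)


class TestFit:
    def test_matches_ols_under_independence(self):
        rng = np.random.default_rng(3)
        n = 1000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y1 = 3.0 + 0.3 * X[:, 1] + rng.normal(0, 0.35, n)
        y2 = 0.8 + rng.normal(0, 0.07, n)
        res = fit_copula_model(y1, y2, X, exog_names=["const", "expr"])
        b_ols = np.linalg.lstsq(X, y1, rcond=None)[0][1]
        assert res.converged
        assert res.wald_test_coef("expr", 1)[0] == pytest.approx(b_ols, abs=1e-3)

    def test_score_vanishes_at_optimum(self):
        y1, y2, X = _simulate_pair(400, beta1=0.2, seed=4)
        res = fit_copula_model(y1, y2, X)
        assert res.score_norm() < 1e-4

    def test_recovers_known_parameters(self):
        y1, y2, X = _simulate_pair(3000, beta1=0.3, beta2=0.05, seed=5)
        res = fit_copula_model(y1, y2, X, exog_names=["const", "expr"])
        b, se, _ = res.wald_test_coef("expr", 1)
        assert b == pytest.approx(0.3, abs=3 * se)
        assert res.margin_params(1)[1] == pytest.approx(0.35, rel=0.1)
        assert res.kendall_tau == pytest.approx(0.36, abs=0.06)

    def test_covariance_symmetric_psd(self):
        y1, y2, X = _simulate_pair(500, seed=6)
        res = fit_copula_model(y1, y2, X)
        cov = res.cov_params()
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        eig = np.linalg.eigvalsh(cov)
        assert eig.min() > -1e-10

    def test_rank_deficient_design_rejected(self):
        y1, y2, X = _simulate_pair(100, seed=7)
        X_bad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            CopulaJointModel(y1, y2, X_bad)

    def test_summary_mentions_copula(self):
        y1, y2, X = _simulate_pair(200, seed=8)
        res = fit_copula_model(y1, y2, X)
        text = res.summary()
        assert "Kendall tau" in text and "phi" in text

    def test_pit_plot_renders(self):
        y1, y2, X = _simulate_pair(150, seed=12)
        res = fit_copula_model(y1, y2, X)
        ax = res.plot_pit()
        assert ax.get_xlabel().startswith("PIT")


class TestDesign:
    def test_dummy_coding_shape(self, small_cohort):
        _, cohort, _, _ = small_cohort
        X, names = build_design(cohort.covariates)
        # intercept + sex + age + 2 smoking + 3 activity + 2 education
        assert X.shape[1] == len(names) == 10
        assert names[0] == "const"
        assert np.all((X[:, 3:] == 0) | (X[:, 3:] == 1))


class TestScreens:
    def test_bonferroni_cutoff(self):
        assert bonferroni_cutoff(0.05, 30917) == pytest.approx(1.6172e-6, rel=1e-4)

    def test_overlap_accounting(self, small_cohort):
        """total = SAT-only + ratio-only + both, and flags respect the cutoff."""
        _, cohort, _, _ = small_cohort
        results, summary = transcriptome_screen(cohort, alpha=0.05)
        assert summary["total"] == (
            summary["sat_only"] + summary["ratio_only"] + summary["both"]
        )
        cutoff = summary["cutoff"]
        ok = results.dropna(subset=["p"])
        assert (ok.loc[ok["significant_sat"], "p"] < cutoff).all()
        assert (ok.loc[~ok["significant_sat"], "p"] >= cutoff).all()

    def test_detects_engineered_genes(self, small_cohort):
        cfg, cohort, _, _ = small_cohort
        results, _ = transcriptome_screen(cohort, alpha=0.05)
        causal = list(cohort.expression.index[: cfg.n_causal])
        assert results.loc[causal, "significant_sat"].all()

    def test_empty_gene_set(self, small_cohort):
        from adipocop.cohort import CohortData

        _, cohort, _, _ = small_cohort
        empty = CohortData(
            expression=cohort.expression.iloc[:0],
            genotypes=cohort.genotypes,
            snv_meta=cohort.snv_meta,
            phenotypes=cohort.phenotypes,
            covariates=cohort.covariates,
        )
        results, summary = transcriptome_screen(empty)
        assert results.empty and summary["total"] == 0

    def test_constant_gene_skipped_but_counted(self, small_cohort):
        from adipocop.cohort import CohortData

        _, cohort, _, _ = small_cohort
        expr = cohort.expression.copy()
        expr.iloc[0] = 5.0
        mutated = CohortData(
            expression=expr,
            genotypes=cohort.genotypes,
            snv_meta=cohort.snv_meta,
            phenotypes=cohort.phenotypes,
            covariates=cohort.covariates,
        )
        results, summary = transcriptome_screen(mutated)
        assert np.isnan(results.iloc[0]["p"])
        assert summary["n_tests"] == len(expr)

    def test_linear_screen_closed_form(self):
        """Covariate-free single gene: OLS slope is cov/var."""
        rng = np.random.default_rng(9)
        n = 200
        g = rng.standard_normal(n)
        y = 1.0 + 0.4 * g + rng.normal(0, 0.3, n)
        X = np.column_stack([np.ones(n), g])
        from adipocop.jointmodel import _ols_last_coef

        b, se, p = _ols_last_coef(y, X)
        expected = np.cov(g, y)[0, 1] / np.var(g, ddof=1)
        assert b == pytest.approx(expected, abs=1e-9)

    def test_copula_matches_linear_in_independence_limit(self):
        """With independent outcomes at n = 2000 the copula Wald p agrees
        with the OLS t-test p to ~10% relative."""
        rng = np.random.default_rng(10)
        n = 2000
        g = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), g])
        y1 = 3.0 + 0.02 * g + rng.normal(0, 0.35, n)
        y2 = 0.8 + rng.normal(0, 0.07, n)
        res = fit_copula_model(y1, y2, X, exog_names=["const", "expr"])
        from adipocop.jointmodel import _ols_last_coef

        _, _, p_lin = _ols_last_coef(y1, X)
        _, _, p_cop = res.wald_test_coef("expr", 1)
        assert p_cop == pytest.approx(p_lin, rel=0.10)

    def test_screen_reproducible(self, small_cohort):
        _, cohort, _, _ = small_cohort
        r1, s1 = transcriptome_screen(cohort, alpha=0.05)
        r2, s2 = transcriptome_screen(cohort, alpha=0.05)
        pd.testing.assert_frame_equal(r1, r2)
        assert s1 == s2
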