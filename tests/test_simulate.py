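"""Synthetic-cohort generator: LD/eQTL oracles, covariate and phenotype
calibration, determinism, fixture round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from adipocop.cohort import MISSING_GENOTYPE
from adipocop.io import read_cohort, write_fixtures
from adipocop.simulate import (
    SimConfig,
    expected_adjacent_genotype_corr,
    make_go_fixture,
    simulate_cohort,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_replication_cohort,
)


class TestConfig:
    def test_invalid_maf_range(self):
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.1, 0.6))

    def test_tau_admissibility(self):
        # phi > 0 requires tau > 1 - 1/theta
        with pytest.raises(ValueError):
            SimConfig(tau=0.36, copula_theta=2.0)
        SimConfig(tau=0.6, copula_theta=2.0)  # admissible

    def test_phi_from_tau(self):
        # algebraic inversion of tau = 1 - 2/(theta*(phi+2)) at theta=1
        assert SimConfig(tau=0.36, copula_theta=1.0).copula_phi == pytest.approx(1.125)


class TestGenotypes:
    def test_independent_snvs_uncorrelated(self):
        cfg = SimConfig(n_samples=10_000, n_genes=2, n_snvs_per_gene=4, ld_decay=0.0, seed=1)
        g, _ = simulate_genotypes(cfg)
        c = np.corrcoef(g.to_numpy(float))
        off = np.abs(c[np.triu_indices_from(c, 1)])
        assert off.mean() < 0.1

    def test_adjacent_correlation_matches_enumeration(self):
        """Sampled genotype correlation equals the exact value enumerated from
        the 9 genotype combinations of the thresholded-haplotype model."""
        cfg = SimConfig(
            n_samples=50_000, n_genes=1, n_snvs_per_gene=2,
            ld_decay=0.95, maf_range=(0.3, 0.3), seed=7,
        )
        g, _ = simulate_genotypes(cfg)
        r = np.corrcoef(g.to_numpy(float))[0, 1]
        exact = expected_adjacent_genotype_corr(0.3, 0.3, 0.95)
        assert r == pytest.approx(exact, abs=0.05)

    def test_maf_half_symmetry(self):
        cfg = SimConfig(n_samples=100_000, n_genes=1, n_snvs_per_gene=2,
                        maf_range=(0.5, 0.5), seed=2)
        g, _ = simulate_genotypes(cfg)
        assert g.to_numpy().mean() == pytest.approx(1.0, abs=0.02)

    def test_meta_layout(self):
        cfg = SimConfig(n_samples=10, n_genes=3, n_snvs_per_gene=2, seed=0)
        g, meta = simulate_genotypes(cfg)
        assert list(meta.columns) == ["chrom", "pos", "ref", "alt", "gene_id", "maf"]
        assert meta["gene_id"].nunique() == 3
        assert (meta["pos"] >= 1).all()


class TestExpression:
    def test_r2_matches_target(self):
        cfg = SimConfig(n_samples=10_000, n_genes=3, n_snvs_per_gene=5,
                        eqtl_r2=0.10, seed=3)
        geno, meta = simulate_genotypes(cfg)
        expr, eqtl, w = simulate_expression(geno, meta, cfg)
        for gene in expr.index:
            idx = (meta["gene_id"] == gene).to_numpy()
            X = np.column_stack([np.ones(cfg.n_samples), geno.loc[idx].to_numpy(float).T])
            y = expr.loc[gene].to_numpy()
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r2 = 1 - ((y - X @ b) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert r2 == pytest.approx(0.10, abs=0.02)

    def test_zero_r2_independent(self):
        cfg = SimConfig(n_samples=1_000, n_genes=1, n_snvs_per_gene=4,
                        eqtl_r2=0.0, seed=4)
        geno, meta = simulate_genotypes(cfg)
        expr, _, _ = simulate_expression(geno, meta, cfg)
        X = np.column_stack([np.ones(1000), geno.to_numpy(float).T])
        y = expr.iloc[0].to_numpy()
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2 = 1 - ((y - X @ b) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 < 0.05

    def test_r2_one_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(eqtl_r2=1.0)

    def test_gtex_layout_columns(self):
        cfg = SimConfig(n_samples=30, n_genes=1, seed=0)
        geno, meta = simulate_genotypes(cfg)
        _, eqtl, _ = simulate_expression(geno, meta, cfg)
        assert {"variant_id", "gene_id", "maf", "slope", "slope_se"} <= set(eqtl.columns)

    def test_expression_nonnegative(self):
        cfg = SimConfig(n_samples=50, n_genes=4, seed=5)
        geno, meta = simulate_genotypes(cfg)
        expr, _, _ = simulate_expression(geno, meta, cfg)
        assert (expr.to_numpy() >= 0).all()


class TestCovariates:
    def test_sex_and_age_calibration(self):
        cov = simulate_covariates(SimConfig(n_samples=100_000, n_genes=1, seed=4))
        women = cov["sex"] == "woman"
        assert women.mean() == pytest.approx(88 / 160, abs=0.01)
        assert cov.loc[women, "age"].mean() == pytest.approx(62.7, abs=0.1)

    def test_single_row_complete(self):
        cov = simulate_covariates(SimConfig(n_samples=1, n_genes=1, seed=0))
        assert len(cov) == 1
        assert not cov.isna().any().any()


class TestPhenotypes:
    def test_residual_tau(self):
        cfg = SimConfig(n_samples=5_000, n_genes=2, seed=5)
        geno, meta = simulate_genotypes(cfg)
        expr, _, _ = simulate_expression(geno, meta, cfg)
        cov = simulate_covariates(cfg)
        ph = simulate_phenotypes(expr, cov, cfg)
        # residualize out the sex/age structure the generator injects
        import statsmodels.api as sm

        X = sm.add_constant(
            pd.get_dummies(cov[["sex", "age"]], drop_first=True, dtype=float)
        )
        r1 = sm.OLS(np.log(ph["SAT"]), X).fit().resid
        r2 = sm.OLS(ph["SAT"] / ph["TAT"], X).fit().resid
        assert kendalltau(r1, r2).statistic == pytest.approx(0.36, abs=0.03)

    def test_plausibility(self, small_cohort):
        _, cohort, _, _ = small_cohort
        sat, tat = cohort.phenotypes["SAT"], cohort.phenotypes["TAT"]
        assert (sat < tat).all()
        assert ((sat / tat > 0) & (sat / tat < 1)).all()

    def test_excessive_clipping_warns(self):
        cfg = SimConfig(n_samples=300, n_genes=2, n_causal=2,
                        beta_ratio=1.0, seed=6)
        geno, meta = simulate_genotypes(cfg)
        expr, _, _ = simulate_expression(geno, meta, cfg)
        cov = simulate_covariates(cfg)
        with pytest.warns(UserWarning, match="clipped"):
            simulate_phenotypes(expr, cov, cfg)


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        cfg = SimConfig(n_samples=40, n_genes=4, seed=9, n_causal=1, beta_sat=0.3)
        a, eq_a, w_a = simulate_cohort(cfg)
        b, eq_b, w_b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(eq_a, eq_b)


class TestReplicationCohort:
    def test_shares_truth_and_masks_snvs(self, small_cohort):
        cfg, cohort, _, weights = small_cohort
        rep_cfg = SimConfig(n_samples=300, n_genes=cfg.n_genes,
                            n_snvs_per_gene=cfg.n_snvs_per_gene, seed=cfg.seed + 1)
        rep = simulate_replication_cohort(rep_cfg, weights, cohort.snv_meta)
        assert {"aSAT", "VAT"} == set(rep.phenotypes.columns)
        assert set(rep.genotypes.index) <= set(cohort.genotypes.index)
        assert 0 < len(rep.genotypes) < len(cohort.genotypes)
        ratio = rep.ratio()
        assert ((ratio > 0) & (ratio < 1)).all()


class TestFixtures:
    def test_round_trip(self, small_cohort, tmp_path):
        _, cohort, eqtl, _ = small_cohort
        cohort = cohort_copy = cohort
        write_fixtures(cohort, tmp_path, eqtl_table=eqtl)
        back = read_cohort(tmp_path)
        np.testing.assert_array_equal(
            back.genotypes.to_numpy(), cohort.genotypes.to_numpy()
        )
        np.testing.assert_allclose(
            back.expression.to_numpy(), cohort.expression.to_numpy()
        )

    def test_missing_genotype_round_trip(self, small_cohort, tmp_path):
        _, cohort, _, _ = small_cohort
        geno = cohort.genotypes.copy()
        geno.iloc[0, 0] = MISSING_GENOTYPE
        from adipocop.cohort import CohortData

        mutated = CohortData(
            expression=cohort.expression,
            genotypes=geno,
            snv_meta=cohort.snv_meta,
            phenotypes=cohort.phenotypes,
            covariates=cohort.covariates,
        )
        write_fixtures(mutated, tmp_path)
        back = read_cohort(tmp_path)
        assert back.genotypes.iloc[0, 0] == MISSING_GENOTYPE
        vcf_text = (tmp_path / "genotypes.vcf").read_text()
        assert "./." in vcf_text

    def test_eqtl_fixture_columns(self, small_cohort, tmp_path):
        _, cohort, eqtl, _ = small_cohort
        paths = write_fixtures(cohort, tmp_path, eqtl_table=eqtl)
        cols = pd.read_csv(paths["eqtl"], sep="\t").columns
        assert {"variant_id", "gene_id"} <= set(cols)

    def test_go_fixture_rooted(self):
        g2g, anc, names = make_go_fixture([f"G{i}" for i in range(20)], seed=3)
        from adipocop.enrichment import AnnotationSet

        ann = AnnotationSet.from_frames(g2g, anc, names)
        assert ann.roots() == {"GO:0008150"}
        leaf = g2g["term_id"].iloc[0]
        assert ann.highest_level_parents(leaf)
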