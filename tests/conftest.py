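import warnings

import matplotlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adipocop.simulate import SimConfig, simulate_cohort

matplotlib.use("Agg")
warnings.filterwarnings("ignore", message=".*ratio values clipped.*")

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cohort():
    """Discovery cohort at desk scale: 160 samples, 8 genes, 2 causal."""
    cfg = SimConfig(
        n_samples=160,
        n_genes=8,
        n_snvs_per_gene=4,
        n_causal=2,
        beta_sat=0.5,
        beta_ratio=0.08,
        eqtl_r2=0.25,
        seed=11,
    )
    cohort, eqtl, weights = simulate_cohort(cfg)
    return cfg, cohort, eqtl, weights


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_filter_fixture(seed=0):
    """160 samples, one gene with 3 eQTL SNVs: v0 is a clean instrument,
    v1 is engineered to predict age (a confounder), v2 duplicates v0.

    Returns ``(cohort, eqtl_table, snv_ids)``; used by the instrument-filter
    tests, which expect exactly v0 to survive filters (i)-(iv).
    """
    from adipocop.cohort import CohortData
    from adipocop.simulate import simulate_covariates

    rng = np.random.default_rng(seed)
    n = 160
    cfg = SimConfig(n_samples=n, n_genes=1, seed=seed)
    cov = simulate_covariates(cfg).copy()
    g0 = rng.binomial(2, 0.3, n)
    g1 = rng.binomial(2, 0.3, n)
    g2 = g0.copy()  # Spearman rho = 1 with v0
    cov["age"] = 60.0 + 4.0 * g1 + rng.normal(0, 2.0, n)  # v1 -> confounder
    expr_latent = 0.5 * g0 + rng.standard_normal(n)
    expression = pd.DataFrame(
        [np.exp(3.0 + 0.3 * expr_latent)], index=["GENE0000"], columns=cov.index
    )
    sat = np.exp(3.0 + 0.1 * expr_latent + rng.normal(0, 0.3, n))
    ratio = np.clip(0.8 + rng.normal(0, 0.05, n), 0.05, 0.95)
    pheno = pd.DataFrame({"SAT": sat, "TAT": sat / ratio}, index=cov.index)
    snv_ids = ["chr1_100_A_G_b38", "chr1_200_A_G_b38", "chr1_300_A_G_b38"]
    genotypes = pd.DataFrame([g0, g1, g2], index=snv_ids, columns=cov.index)
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [100, 200, 300],
            "ref": "A",
            "alt": "G",
            "gene_id": "GENE0000",
            "maf": 0.3,
        },
        index=pd.Index(snv_ids, name="variant_id"),
    )
    cohort = CohortData(
        expression=expression,
        genotypes=genotypes,
        snv_meta=meta,
        phenotypes=pheno,
        covariates=cov,
    )
    eqtl = pd.DataFrame({"variant_id": snv_ids, "gene_id": "GENE0000"})
    return cohort, eqtl, snv_ids
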