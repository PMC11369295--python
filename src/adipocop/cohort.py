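"""Aligned sample-indexed container for one cohort.

A :class:`CohortData` bundles everything one analysis cohort provides:
normalized expression (genes x samples), additive-coded genotypes
(SNVs x samples, ``-1`` marking missing calls), SNV metadata, adipose-tissue
phenotypes and the five epidemiological covariates.  All tables share the
sample axis and are validated on construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ["sex", "age", "smoking", "physical_activity", "education"]

SMOKING_LEVELS = ["never", "former", "current"]
ACTIVITY_LEVELS = ["inactive", "moderately_inactive", "moderately_active", "active"]
EDUCATION_LEVELS = ["vocational", "technical_college", "university"]
SEX_LEVELS = ["woman", "man"]

MISSING_GENOTYPE = -1


@dataclass
class CohortData:
    """One cohort's aligned matrices and tables.

    Attributes
    ----------
    expression : DataFrame, genes x samples, non-negative normalized counts.
    genotypes : DataFrame, SNVs x samples, entries in {0, 1, 2} or -1 (missing).
    snv_meta : DataFrame indexed by SNV id with columns ``chrom``, ``pos``
        (1-based), ``ref``, ``alt``, ``gene_id`` and optionally ``maf``.
    phenotypes : DataFrame indexed by sample with ``SAT``/``TAT`` (discovery)
        or ``aSAT``/``VAT`` (replication), all in kg.
    covariates : DataFrame with sex, age, smoking, physical_activity, education.
    """

    expression: pd.DataFrame
    genotypes: pd.DataFrame
    snv_meta: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotypes.index

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        samples = self.phenotypes.index
        for name in ("expression", "genotypes"):
            df = getattr(self, name)
            if not df.columns.equals(samples):
                raise ValueError(f"{name} columns do not match the sample axis")
        if not self.covariates.index.equals(samples):
            raise ValueError("covariates index does not match the sample axis")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression contains negative values")
        g = self.genotypes.to_numpy()
        ok = np.isin(g, (0, 1, 2, MISSING_GENOTYPE))
        if not ok.all():
            raise ValueError("genotypes must be 0/1/2 or -1 (missing)")
        if not self.snv_meta.index.equals(self.genotypes.index):
            raise ValueError("snv_meta index does not match genotype rows")
        if {"SAT", "TAT"} <= set(self.phenotypes.columns):
            sat = self.phenotypes["SAT"].to_numpy()
            tat = self.phenotypes["TAT"].to_numpy()
            if (sat <= 0).any() or (tat <= 0).any():
                raise ValueError("SAT and TAT must be positive")
            if (sat > tat).any():
                raise ValueError("SAT must not exceed TAT")

    def ratio(self) -> pd.Series:
        """SAT/TAT (discovery) or aSAT/(aSAT+VAT) (replication), in (0, 1)."""
        ph = self.phenotypes
        if "TAT" in ph.columns:
            return ph["SAT"] / ph["TAT"]
        return ph["aSAT"] / (ph["aSAT"] + ph["VAT"])
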