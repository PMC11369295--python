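"""TWAS-style replication in an independent cohort.

For each causal gene, the discovery cohort provides per-SNV weights from one
multiple linear regression of (transformed) expression on the gene's
surviving instruments.  In the replication cohort the genetically-determined
expression score is the weighted allele-count sum restricted to the SNVs its
sequencing actually covers (weights are never refit), and the score is tested
against log aSAT and aSAT/(aSAT+VAT) in a linear model adjusting for age,
sex, smoking and education.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .jointmodel import build_design
from .mr import _impute_missing
from .preprocess import yeo_johnson

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationModel",
    "ReplicationResult",
    "learn_weights",
    "impute_expression",
    "replication_test",
    "replication_pipeline",
]

REPLICATION_COVARIATES = ["sex", "age", "smoking", "education"]


@dataclass
class ImputationModel:
    """Per-gene SNV weights for expression imputation in a second cohort."""

    gene_id: str
    snv_ids: list[str]
    weights: np.ndarray
    intercept: float
    training_r2: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snv_ids) < 1 or len(self.weights) != len(self.snv_ids):
            raise ValueError("need >= 1 SNV with one weight each")
        if not (0 <= self.training_r2 <= 1):
            raise ValueError("training r2 must lie in [0, 1]")

    def restricted_r2(self, available: list[str], genotypes_a: pd.DataFrame,
                      expression_a: np.ndarray) -> float:
        """Discovery-cohort R^2 of the score restricted to ``available`` SNVs."""
        G = _impute_missing(genotypes_a.loc[available].to_numpy())
        score = self.intercept + np.array(
            [self.weights[self.snv_ids.index(v)] for v in available]
        ) @ G
        y = np.asarray(expression_a, dtype=float)
        if np.ptp(score) == 0:
            return 0.0
        return float(np.corrcoef(score, y)[0, 1] ** 2)


@dataclass
class ReplicationResult:
    gene_id: str
    outcome: str  # 'aSAT' or 'aSAT_fraction'
    n_var_available: int
    r2_available: float
    beta: float
    se: float
    p: float


def learn_weights(expr_gene, genotypes: pd.DataFrame) -> ImputationModel:
    """OLS of a gene's (transformed) expression on all its instruments jointly.

    Collinear instruments are reduced to a full-rank subset (kept in genomic
    order) before fitting; the dropped SNVs are logged and excluded from the
    model.
    """
    y = np.asarray(expr_gene, dtype=float)
    snv_ids = list(genotypes.index)
    G = _impute_missing(genotypes.to_numpy())
    if G.shape[1] != len(y):
        raise ValueError("genotype/expression sample mismatch")
    if G.shape[1] <= G.shape[0] + 1:
        raise ValueError("need n > n_var + 1 observations")
    keep = _full_rank_subset(G)
    if len(keep) < len(snv_ids):
        dropped = [snv_ids[i] for i in range(len(snv_ids)) if i not in keep]
        logger.info("dropped collinear SNVs: %s", dropped)
    G = G[keep]
    snv_ids = [snv_ids[i] for i in keep]
    X = np.column_stack([np.ones(G.shape[1]), G.T])
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ b
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - np.sum((y - fitted) ** 2) / ss_tot) if ss_tot > 0 else 0.0
    return ImputationModel(
        gene_id=getattr(expr_gene, "name", "gene"),
        snv_ids=snv_ids,
        weights=b[1:],
        intercept=float(b[0]),
        training_r2=max(0.0, min(1.0, r2)),
    )


def _full_rank_subset(G: np.ndarray) -> list[int]:
    """Indices of a maximal leading full-rank row subset (with intercept)."""
    keep: list[int] = []
    n = G.shape[1]
    base = np.ones((n, 1))
    for i in range(G.shape[0]):
        cand = np.column_stack([base] + [G[j][:, None] for j in keep + [i]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(i)
    return keep


def impute_expression(
    model: ImputationModel, genotypes_b: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """Genetically-determined expression score in cohort B.

    Uses the discovery weights restricted to the model SNVs present in
    ``genotypes_b`` (no refitting).  Returns ``(score, available_snvs)``;
    raises if no model SNV is available.
    """
    available = [v for v in model.snv_ids if v in genotypes_b.index]
    if not available:
        raise ValueError(f"gene {model.gene_id}: no model SNV available in cohort B")
    w = np.array([model.weights[model.snv_ids.index(v)] for v in available])
    G = _impute_missing(genotypes_b.loc[available].to_numpy())
    score = model.intercept + w @ G
    return pd.Series(score, index=genotypes_b.columns, name=model.gene_id), available


def replication_test(
    score: pd.Series,
    phenotypes_b: pd.DataFrame,
    covariates_b: pd.DataFrame,
    outcome: str = "aSAT",
) -> tuple[float, float, float]:
    """Covariate-adjusted linear association of the imputed score.

    ``outcome`` is 'aSAT' (log-transformed) or 'aSAT_fraction'
    (aSAT/(aSAT+VAT), untransformed).  Adjusts for age, sex, smoking and
    education; two-sided t-test on the score coefficient.

    Returns ``(beta, se, p)``.
    """
    if np.ptp(score.to_numpy()) == 0:
        raise ValueError("imputed score is constant")
    if outcome == "aSAT":
        y = np.log(phenotypes_b["aSAT"].to_numpy(dtype=float))
    elif outcome == "aSAT_fraction":
        asat = phenotypes_b["aSAT"].to_numpy(dtype=float)
        vat = phenotypes_b["VAT"].to_numpy(dtype=float)
        y = asat / (asat + vat)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    X0, _ = build_design(covariates_b, columns=REPLICATION_COVARIATES)
    X = np.column_stack([X0, score.to_numpy()])
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    s2 = resid @ resid / (n - k)
    se = np.sqrt(s2 * XtX_inv[-1, -1])
    tval = b[-1] / se
    return float(b[-1]), float(se), float(2.0 * t_dist.sf(abs(tval), n - k))


def replication_pipeline(
    mr_results: pd.DataFrame,
    instruments: dict,
    cohort_a,
    cohort_b,
    alpha: float = 0.05,
    pre_transformed: bool = False,
):
    """Replicate each causal gene on its matching outcome in cohort B.

    ``mr_results`` is the MR screen table; only rows flagged causal are
    followed up.  ``instruments`` maps (gene, outcome) -> InstrumentSet from
    the discovery MR.  The discovery exposure (Yeo-Johnson expression unless
    ``pre_transformed``) is regressed on the surviving SNVs to learn weights,
    the score is imputed from cohort B's available SNVs, and the association
    is tested against log aSAT ('sat' genes) or aSAT/(aSAT+VAT) ('ratio'
    genes).

    Returns ``(results_table, counts)`` with investigated/confirmed counts.
    """
    rows = []
    investigated = confirmed = 0
    causal = mr_results.loc[mr_results["causal"]]
    for _, row in causal.iterrows():
        gene, outcome = row["gene_id"], row["outcome"]
        inst = instruments.get((gene, outcome))
        if inst is None:
            continue
        expr = cohort_a.expression.loc[gene].to_numpy(dtype=float)
        if not pre_transformed:
            expr, _ = yeo_johnson(expr)
        model = learn_weights(
            pd.Series(expr, name=gene), cohort_a.genotypes.loc[inst.snv_ids]
        )
        try:
            score, available = impute_expression(model, cohort_b.genotypes)
        except ValueError:
            logger.info("gene %s: no SNV available in replication cohort", gene)
            continue
        investigated += 1
        rep_outcome = "aSAT" if outcome == "sat" else "aSAT_fraction"
        beta, se, p = replication_test(
            score, cohort_b.phenotypes, cohort_b.covariates, outcome=rep_outcome
        )
        r2_avail = model.restricted_r2(
            available, cohort_a.genotypes, expr
        )
        ok = p < alpha
        confirmed += int(ok)
        rows.append(
            (gene, rep_outcome, len(available), r2_avail, beta, se, p, ok)
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "outcome",
            "n_var_available",
            "r2_available",
            "beta",
            "se",
            "p",
            "confirmed",
        ],
    )
    counts = {"investigated": investigated, "confirmed": confirmed}
    return results, counts
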