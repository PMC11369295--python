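"""Per-gene Mendelian randomization with correlated instruments.

Instrument selection applies four filters to the cohort's SNVs:

(i)   membership in the gene's rows of a cis-eQTL table (GTEx
      ``signif_variant_gene_pairs`` layout);
(ii)  no association with any covariate (sex, age, smoking, physical
      activity, education) at p < 0.001 — linear-regression Wald tests for
      continuous covariates, Fisher's exact tests on genotype x category
      tables for categorical ones;
(iii) no association with the outcome conditional on the gene's expression
      and the covariates, at p < 0.001;
(iv)  LD pruning: of each SNV pair with |Spearman rho| > 0.9, the one with
      the weaker eQTL association is dropped.

The causal effect is the inverse-variance-weighted estimate for correlated
instruments: a generalized least-squares fit of the per-SNV outcome effects
on the exposure effects through the origin.  With first-order weights the
weighting matrix is the outcome-effect covariance; delta weights add the
second-order exposure-uncertainty terms and the exposure-outcome sample
correlation ``psi`` (form frozen against a parametric bootstrap of the
summary-statistic covariance):

    Omega_ij = rho_ij se_by_i se_by_j
             + theta0^2 rho_ij se_bx_i se_bx_j
             - theta0 psi rho_ij (se_bx_i se_by_j + se_by_i se_bx_j)

with ``theta0`` the first-order estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact, norm, random_table, spearmanr, t as t_dist

from .cohort import MISSING_GENOTYPE
from .jointmodel import build_design
from .preprocess import transform_phenotypes, yeo_johnson

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "IVWModel",
    "IVWResults",
    "MRResult",
    "categorical_exact_pvalue",
    "select_instruments",
    "ivw_correlated",
    "mr_screen",
]

_CATEGORICAL = ("sex", "smoking", "physical_activity", "education")
_CONTINUOUS = ("age",)


@dataclass
class InstrumentSet:
    """Surviving instruments for one gene/outcome with their summary stats."""

    gene_id: str
    outcome: str
    snv_ids: list[str]
    bx: np.ndarray
    se_bx: np.ndarray
    by: np.ndarray
    se_by: np.ndarray
    rho: np.ndarray
    psi_mr: float
    r2: float

    def __post_init__(self) -> None:
        m = len(self.snv_ids)
        for name in ("bx", "se_bx", "by", "se_by"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (m,):
                raise ValueError(f"{name} length mismatch")
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (m, m):
            raise ValueError("rho must be m x m")
        if not np.allclose(self.rho, self.rho.T) or not np.allclose(np.diag(self.rho), 1):
            raise ValueError("rho must be symmetric with unit diagonal")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("rho entries must lie in [-1, 1]")
        if not (0 <= self.r2 <= 1):
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def n_var(self) -> int:
        return len(self.snv_ids)


@dataclass
class MRResult:
    gene_id: str
    outcome: str
    theta: float
    se: float
    p: float
    n_var: int
    r2: float


def _impute_missing(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing genotype calls (-1) per SNV."""
    G = G.astype(float)
    miss = G == MISSING_GENOTYPE
    if miss.any():
        for i in np.flatnonzero(miss.any(axis=1)):
            row = G[i]
            row[miss[i]] = row[~miss[i]].mean() if (~miss[i]).any() else 0.0
    return G


def _ols_coef_p(y: np.ndarray, X: np.ndarray, col: int):
    """(coef, se, two-sided t p) for one design column by OLS."""
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    dof = n - np.linalg.matrix_rank(X)
    s2 = resid @ resid / dof
    se = np.sqrt(max(s2 * XtX_inv[col, col], 1e-300))
    tval = b[col] / se
    return b[col], se, 2.0 * t_dist.sf(abs(tval), dof)


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of an r x c table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def categorical_exact_pvalue(
    genotype: np.ndarray, category: np.ndarray, rng=None, n_mc: int = 4999
) -> float:
    """Fisher's exact test of a genotype x category contingency table.

    2x2 tables are evaluated exactly; larger tables use a seeded Monte-Carlo
    conditional test (Patefield sampling of tables with the observed margins,
    table-probability statistic), the same construction as simulated exact
    tests in standard statistical software.
    """
    gl = np.unique(genotype)
    cl = np.unique(category)
    if len(gl) < 2 or len(cl) < 2:
        return 1.0
    table = np.zeros((len(gl), len(cl)), dtype=int)
    for i, g in enumerate(gl):
        for j, c in enumerate(cl):
            table[i, j] = int(np.sum((genotype == g) & (category == c)))
    if table.shape == (2, 2):
        return float(fisher_exact(table).pvalue)
    rng = np.random.default_rng(rng)
    dist = random_table(table.sum(axis=1), table.sum(axis=0))
    sims = dist.rvs(n_mc, random_state=rng)
    obs = _log_table_prob(table)
    margin_const = (
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(table.sum() + 1)
    )
    lp = margin_const - gammaln(sims + 1).sum(axis=(1, 2))
    hits = int(np.sum(lp <= obs + 1e-7))
    return (hits + 1) / (n_mc + 1)


def select_instruments(
    gene: str,
    outcome_name: str,
    eqtl_table: pd.DataFrame,
    cohort,
    expression_row: np.ndarray | None = None,
    p_thresh: float = 0.001,
    rho_max: float = 0.9,
    seed: int = 0,
) -> InstrumentSet | None:
    """Apply the four instrument filters and assemble summary statistics.

    ``outcome_name`` is 'sat' (log SAT) or 'ratio' (SAT/TAT).  Returns None
    when no SNV survives.  Per-SNV exposure (``bx``) and outcome (``by``)
    effects come from covariate-adjusted linear regressions on the same
    individual-level data; ``rho`` is the Pearson genotype correlation among
    survivors and ``psi_mr`` the sample correlation between the transformed
    expression and the analysis-scale outcome.
    """
    # (i) cis-eQTL membership
    in_eqtl = set(eqtl_table.loc[eqtl_table["gene_id"] == gene, "variant_id"])
    candidates = [v for v in cohort.genotypes.index if v in in_eqtl]
    if not candidates:
        logger.info("gene %s: no eQTL SNVs in cohort", gene)
        return None

    ph = transform_phenotypes(cohort.phenotypes)
    y = ph["log_sat"].to_numpy() if outcome_name == "sat" else ph["ratio"].to_numpy()
    if expression_row is None:
        expression_row, _ = yeo_johnson(cohort.expression.loc[gene].to_numpy(dtype=float))
    expr = np.asarray(expression_row, dtype=float)
    Xcov, _ = build_design(cohort.covariates)
    cov_df = cohort.covariates
    G = _impute_missing(cohort.genotypes.loc[candidates].to_numpy())
    rng = np.random.default_rng(seed)

    # (ii) confounder association, (iii) outcome association given expression
    keep = []
    for i, vid in enumerate(candidates):
        g = G[i]
        if np.ptp(g) == 0:
            continue
        confounded = False
        for col in _CONTINUOUS:
            X = np.column_stack([np.ones_like(g), g])
            _, _, p = _ols_coef_p(cov_df[col].to_numpy(dtype=float), X, 1)
            if p < p_thresh:
                confounded = True
                break
        if not confounded:
            g_round = np.round(g).astype(int)  # imputed dosages back to classes
            for col in _CATEGORICAL:
                p = categorical_exact_pvalue(g_round, cov_df[col].to_numpy(), rng=rng)
                if p < p_thresh:
                    confounded = True
                    break
        if confounded:
            continue
        X = np.column_stack([Xcov, expr, g])
        _, _, p = _ols_coef_p(y, X, X.shape[1] - 1)
        if p < p_thresh:
            continue
        keep.append(i)
    if not keep:
        logger.info("gene %s/%s: no SNV survives filters (ii)-(iii)", gene, outcome_name)
        return None

    # eQTL association strength drives the pruning order
    order = []
    for i in keep:
        Xg = np.column_stack([Xcov, G[i]])
        _, _, p = _ols_coef_p(expr, Xg, Xg.shape[1] - 1)
        pos = int(cohort.snv_meta.loc[candidates[i], "pos"])
        order.append((p, pos, i))
    order.sort()

    # (iv) greedy Spearman pruning, strongest eQTL first, position tie-break
    survivors: list[int] = []
    for _, _, i in order:
        ok = True
        for j in survivors:
            r = spearmanr(G[i], G[j]).statistic
            if np.isfinite(r) and abs(r) > rho_max:
                ok = False
                break
        if ok:
            survivors.append(i)
    survivors.sort()  # restore genomic order

    snv_ids = [candidates[i] for i in survivors]
    Gs = G[survivors]
    bx = np.empty(len(survivors))
    se_bx = np.empty(len(survivors))
    by = np.empty(len(survivors))
    se_by = np.empty(len(survivors))
    for k, i in enumerate(survivors):
        Xg = np.column_stack([Xcov, G[i]])
        bx[k], se_bx[k], _ = _ols_coef_p(expr, Xg, Xg.shape[1] - 1)
        by[k], se_by[k], _ = _ols_coef_p(y, Xg, Xg.shape[1] - 1)
    rho = np.corrcoef(Gs) if len(survivors) > 1 else np.ones((1, 1))
    psi = float(np.corrcoef(expr, y)[0, 1])
    Xfull = np.column_stack([np.ones(Gs.shape[1]), Gs.T])
    bhat, *_ = np.linalg.lstsq(Xfull, expr, rcond=None)
    resid = expr - Xfull @ bhat
    r2 = float(1.0 - resid @ resid / np.sum((expr - expr.mean()) ** 2))
    return InstrumentSet(
        gene_id=gene,
        outcome=outcome_name,
        snv_ids=snv_ids,
        bx=bx,
        se_bx=se_bx,
        by=by,
        se_by=se_by,
        rho=rho,
        psi_mr=psi,
        r2=max(0.0, min(1.0, r2)),
    )


class IVWModel:
    """Inverse-variance-weighted MR estimator for correlated instruments.

    GLS regression of outcome effects on exposure effects through the origin:
    ``theta = (bx' W bx)^-1 bx' W by`` with ``W = Omega^-1``.
    """

    def __init__(self, inst: InstrumentSet):
        self.inst = inst

    def _solve(self, omega: np.ndarray):
        m = omega.shape[0]
        try:
            Wbx = np.linalg.solve(omega, self.inst.bx)
            Wby = np.linalg.solve(omega, self.inst.by)
        except np.linalg.LinAlgError:
            omega = omega + 1e-8 * np.eye(m)
            logger.info("singular Omega for %s; ridge 1e-8 added", self.inst.gene_id)
            Wbx = np.linalg.solve(omega, self.inst.bx)
            Wby = np.linalg.solve(omega, self.inst.by)
        denom = self.inst.bx @ Wbx
        if denom <= 0:
            raise np.linalg.LinAlgError("Omega not positive definite after ridge")
        theta = (self.inst.bx @ Wby) / denom
        se = np.sqrt(1.0 / denom)
        return theta, se

    def fit(self, weights: str = "delta") -> "IVWResults":
        inst = self.inst
        omega1 = inst.rho * np.outer(inst.se_by, inst.se_by)
        theta0, se0 = self._solve(omega1)
        if weights == "first_order":
            theta, se = theta0, se0
        elif weights == "delta":
            cross = np.outer(inst.se_bx, inst.se_by) + np.outer(inst.se_by, inst.se_bx)
            omega = (
                omega1
                + theta0**2 * inst.rho * np.outer(inst.se_bx, inst.se_bx)
                - theta0 * inst.psi_mr * inst.rho * cross
            )
            theta, se = self._solve(omega)
        else:
            raise ValueError(f"unknown weights {weights!r}")
        p = float(2.0 * norm.sf(abs(theta / se)))
        return IVWResults(self, theta, se, p, weights)


@dataclass
class IVWResults:
    model: IVWModel
    theta: float
    se: float
    p: float
    weights: str

    def as_mr_result(self) -> MRResult:
        inst = self.model.inst
        return MRResult(
            gene_id=inst.gene_id,
            outcome=inst.outcome,
            theta=self.theta,
            se=self.se,
            p=self.p,
            n_var=inst.n_var,
            r2=inst.r2,
        )

    def summary(self) -> str:
        inst = self.model.inst
        return (
            f"IVW ({self.weights} weights), gene {inst.gene_id}, outcome {inst.outcome}\n"
            f"instruments: {inst.n_var}, instrument R^2 = {inst.r2:.3f}, "
            f"psi = {inst.psi_mr:.3f}\n"
            f"theta = {self.theta:.4f} (SE {self.se:.4f}), p = {self.p:.3g}"
        )


def ivw_correlated(inst: InstrumentSet, weights: str = "delta") -> MRResult:
    """Convenience wrapper: fit the IVW model and return an :class:`MRResult`."""
    return IVWModel(inst).fit(weights=weights).as_mr_result()


def mr_screen(
    assoc_genes: dict[str, list[str]],
    eqtl_table: pd.DataFrame,
    cohort,
    alpha: float = 0.05,
    p_thresh: float = 0.001,
    rho_max: float = 0.9,
    weights: str = "delta",
    seed: int = 0,
):
    """MR over the associated genes, per relevant outcome.

    ``assoc_genes`` maps outcome name ('sat', 'ratio') to the genes to test
    against that outcome.  Returns ``(results, summary)`` with Table-4-style
    counts (analyzable and causal genes per outcome) and mean instrument
    count / R^2 diagnostics.
    """
    rows = []
    counts = {}
    for outcome, genes in assoc_genes.items():
        analyzable = 0
        causal = 0
        nvars, r2s = [], []
        for gene in genes:
            inst = select_instruments(
                gene, outcome, eqtl_table, cohort,
                p_thresh=p_thresh, rho_max=rho_max, seed=seed,
            )
            if inst is None:
                continue
            analyzable += 1
            res = ivw_correlated(inst, weights=weights)
            nvars.append(res.n_var)
            r2s.append(res.r2)
            sig = res.p < alpha
            causal += int(sig)
            rows.append(
                (gene, outcome, res.theta, res.se, res.p, res.n_var, res.r2, sig)
            )
        counts[outcome] = {
            "tested": len(genes),
            "analyzable": analyzable,
            "causal": causal,
            "mean_n_var": float(np.mean(nvars)) if nvars else 0.0,
            "mean_r2": float(np.mean(r2s)) if r2s else 0.0,
        }
    results = pd.DataFrame(
        rows,
        columns=["gene_id", "outcome", "theta", "se", "p", "n_var", "r2", "causal"],
    )
    return results, counts
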