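"""Joint copula model of (log SAT, SAT/TAT) and the per-gene screens.

The joint distribution of the two outcomes given covariates and one gene's
expression is built from two linear-Gaussian marginal regressions coupled by
the two-parameter BB1 copula:

    F(y1, y2 | x) = C_{phi,theta}( F1(y1 | x), F2(y2 | x) )

    y1 = log SAT   = X gamma  + beta_j g_j + eps,   eps  ~ N(0, sigma^2)
    y2 = SAT/TAT   = X gamma' + beta'_j g_j + eps', eps' ~ N(0, sigma'^2)

All free parameters (both marginal coefficient vectors, both residual scales
and the copula pair) are estimated by one-stage maximum likelihood on an
unconstrained parameterization (log sigma, log phi, log(theta-1)); the
covariance of the estimates is the inverse observed information, and the
exposure coefficients are tested with two-sided large-sample Wald tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import kendalltau, norm, t as t_dist
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .cohort import (
    ACTIVITY_LEVELS,
    COVARIATE_COLUMNS,
    EDUCATION_LEVELS,
    SEX_LEVELS,
    SMOKING_LEVELS,
)
from .copula import CopulaParams, bb1_logdensity, bb1_tau, bb1_tau_inverse_phi
from .preprocess import transform_phenotypes, yeo_johnson

logger = logging.getLogger(__name__)

__all__ = [
    "CopulaJointModel",
    "CopulaJointResults",
    "joint_loglik",
    "fit_copula_model",
    "build_design",
    "transcriptome_screen",
    "linear_screen",
    "bonferroni_cutoff",
    "overlap_counts",
]

_LEVELS = {
    "sex": SEX_LEVELS,
    "smoking": SMOKING_LEVELS,
    "physical_activity": ACTIVITY_LEVELS,
    "education": EDUCATION_LEVELS,
}
_U_EPS = 1e-10
_LOG_2PI = np.log(2.0 * np.pi)


def build_design(covariates: pd.DataFrame, columns=None):
    """Intercept + dummy-coded covariate design matrix.

    Categorical covariates are dummy-coded against their first level;
    continuous columns enter as-is.  Returns ``(X, names)``.
    """
    columns = COVARIATE_COLUMNS if columns is None else list(columns)
    parts = [np.ones((len(covariates), 1))]
    names = ["const"]
    for col in columns:
        if col not in covariates.columns:
            raise KeyError(f"covariate {col!r} missing")
        if col in _LEVELS:
            values = covariates[col].to_numpy()
            for level in _LEVELS[col][1:]:
                parts.append((values == level).astype(float)[:, None])
                names.append(f"{col}[{level}]")
        else:
            parts.append(covariates[col].to_numpy(dtype=float)[:, None])
            names.append(col)
    return np.hstack(parts), names


class CopulaJointModel:
    """Bivariate Gaussian-margin BB1-copula regression model.

    Parameters
    ----------
    y1, y2 : outcome vectors (log SAT and SAT/TAT on the analysis scale).
    exog : design matrix shared by both margins (intercept included).
    exog_names : optional column names for reporting.

    The free-parameter vector is laid out as
    ``[gamma1 (k), log sigma1, gamma2 (k), log sigma2, log phi, log(theta-1)]``.
    """

    def __init__(self, y1, y2, exog, exog_names=None):
        self.y1 = np.asarray(y1, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        n, k = self.exog.shape
        if len(self.y1) != n or len(self.y2) != n:
            raise ValueError("outcome/exog dimensions disagree")
        if n <= 2 * k + 4:
            raise ValueError("need more observations than free parameters")
        if np.linalg.matrix_rank(self.exog) < k:
            raise ValueError("design matrix is rank deficient")
        self.k_exog = k
        self.nobs = n
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{i}" for i in range(k)]
        )

    # -- parameter bookkeeping -------------------------------------------
    @property
    def k_params(self) -> int:
        return 2 * self.k_exog + 4

    def _unpack(self, params):
        k = self.k_exog
        g1 = params[:k]
        ls1 = params[k]
        g2 = params[k + 1 : 2 * k + 1]
        ls2 = params[2 * k + 1]
        lphi = params[2 * k + 2]
        ltm1 = params[2 * k + 3]
        return g1, ls1, g2, ls2, lphi, ltm1

    def param_names(self):
        names = [f"sat:{n}" for n in self.exog_names] + ["sat:log_sigma"]
        names += [f"ratio:{n}" for n in self.exog_names] + ["ratio:log_sigma"]
        names += ["copula:log_phi", "copula:log_theta_m1"]
        return names

    # -- likelihood -------------------------------------------------------
    def loglike(self, params) -> float:
        g1, ls1, g2, ls2, lphi, ltm1 = self._unpack(np.asarray(params, dtype=float))
        s1, s2 = np.exp(ls1), np.exp(ls2)
        phi = np.exp(lphi)
        theta = 1.0 + np.exp(ltm1)
        r1 = (self.y1 - self.exog @ g1) / s1
        r2 = (self.y2 - self.exog @ g2) / s2
        ll_marg = -0.5 * (r1 * r1 + r2 * r2).sum() - self.nobs * (
            _LOG_2PI + ls1 + ls2
        )
        u1 = np.clip(ndtr(r1), _U_EPS, 1.0 - _U_EPS)
        u2 = np.clip(ndtr(r2), _U_EPS, 1.0 - _U_EPS)
        try:
            ll_cop = float(np.sum(bb1_logdensity(u1, u2, (phi, theta))))
        except FloatingPointError:
            return -np.inf
        return ll_marg + ll_cop

    def _start_params(self):
        X = self.exog
        b1, *_ = np.linalg.lstsq(X, self.y1, rcond=None)
        b2, *_ = np.linalg.lstsq(X, self.y2, rcond=None)
        r1 = self.y1 - X @ b1
        r2 = self.y2 - X @ b2
        s1 = max(r1.std(), 1e-8)
        s2 = max(r2.std(), 1e-8)
        tau = kendalltau(r1, r2).statistic
        tau = min(max(tau if np.isfinite(tau) else 0.0, 1e-3), 0.95)
        phi0 = bb1_tau_inverse_phi(tau, 1.0) if tau > 0 else 1e-3
        phi0 = max(phi0, 1e-3)
        return np.concatenate(
            [b1, [np.log(s1)], b2, [np.log(s2)], [np.log(phi0)], [np.log(1e-3)]]
        )

    def _standardizer(self):
        """Column centering/scaling for optimization, with the exact linear
        map sending standardized-scale parameters back to the data scale.

        Non-constant design columns are centered and scaled to unit sd; the
        two outcomes are centered and scaled as well (their scale folds into
        log sigma additively, their location into the intercept).  The
        likelihood is invariant up to a constant, so estimates, covariance
        and Wald tests transform back exactly.
        """
        X = self.exog
        mx = X.mean(axis=0)
        sx = X.std(axis=0)
        const = sx < 1e-12
        mx[const] = 0.0
        sx[const] = 1.0
        has_const = bool(const.any())
        my1, sy1 = self.y1.mean(), max(self.y1.std(), 1e-12)
        my2, sy2 = self.y2.mean(), max(self.y2.std(), 1e-12)
        Xs = (X - mx) / sx
        Xs[:, const] = 1.0

        k = self.k_exog
        # gamma_orig = sy * T gamma_std + e0 * my, with T absorbing column scaling
        T = np.diag(1.0 / sx)
        if has_const:
            j0 = int(np.argmax(const))
            T[j0, :] = -mx / sx
            T[j0, j0] = 1.0
        else:
            j0 = None

        def to_data_scale(params_std):
            p = np.array(params_std, dtype=float)
            out = p.copy()
            for off, sy, my in ((0, sy1, my1), (k + 1, sy2, my2)):
                g = p[off : off + k]
                gd = sy * (T @ g)
                if j0 is not None:
                    gd[j0] += my
                out[off : off + k] = gd
                out[off + k] = p[off + k] + np.log(sy)
            return out

        # Jacobian of the map (constant): block diag [sy*T, 1] twice, I_2
        A = np.eye(self.k_params)
        for off, sy in ((0, sy1), (k + 1, sy2)):
            A[off : off + k, off : off + k] = sy * T
        return Xs, (my1, sy1), (my2, sy2), to_data_scale, A

    def fit(self, start_params=None, maxiter=500, n_restarts=2) -> "CopulaJointResults":
        """Maximize the joint likelihood by L-BFGS-B on the unconstrained scale.

        Internally the design columns and outcomes are standardized for
        conditioning and the estimates mapped back exactly.  On failure the
        optimizer restarts from deterministically perturbed starts; a fit
        that still fails is returned with ``converged=False`` (its Wald
        p-values are reported as NaN by the screen).
        """
        Xs, (my1, sy1), (my2, sy2), to_data, A = self._standardizer()
        inner = CopulaJointModel.__new__(CopulaJointModel)
        inner.y1 = (self.y1 - my1) / sy1
        inner.y2 = (self.y2 - my2) / sy2
        inner.exog = Xs
        inner.k_exog = self.k_exog
        inner.nobs = self.nobs
        inner.exog_names = self.exog_names
        res_std = inner._fit_raw(start_params, maxiter, n_restarts)
        params = to_data(res_std.params)
        cov = A @ res_std.cov_params() @ A.T
        # loglik back on the data scale: subtract the Jacobian constant
        llf = res_std.llf - self.nobs * (np.log(sy1) + np.log(sy2))
        return CopulaJointResults(self, params, llf, cov, res_std.converged)

    def _fit_raw(self, start_params=None, maxiter=500, n_restarts=2) -> "CopulaJointResults":
        start = self._start_params() if start_params is None else np.asarray(start_params, float)
        bounds = [(None, None)] * self.k_exog + [(-12.0, 8.0)]
        bounds += [(None, None)] * self.k_exog + [(-12.0, 8.0)]
        bounds += [(-10.0, 6.0), (-12.0, 4.0)]

        def neg(p):
            v = self.loglike(p)
            return np.inf if not np.isfinite(v) else -v

        best = None
        x0 = start.copy()
        for attempt in range(n_restarts + 1):
            res = minimize(
                neg,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": maxiter,
                    "maxfun": 20000,
                    "ftol": 1e-11,
                    "gtol": 1e-7,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
            x0 = start * 1.05 + 0.01 * (attempt + 1)
        params, fval, H = self._newton_polish(best.x, neg)
        cov = _robust_inverse(H)
        return CopulaJointResults(self, params, -fval, cov, bool(best.success))

    def _newton_polish(self, params, neg, max_steps: int = 4, tol: float = 1e-6):
        """Damped Newton refinement so the score vanishes at the reported optimum.

        L-BFGS-B stops on function decrease; a few Newton steps with the
        centered-difference gradient and observed Hessian drive the gradient
        max-norm to the finite-difference noise floor.  Returns the refined
        parameters, objective value, and the Hessian at the final point.
        """
        fval = neg(params)
        H = approx_hess(params, neg)
        for _ in range(max_steps):
            g = approx_fprime(params, neg, centered=True)
            if np.max(np.abs(g)) < tol:
                break
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            improved = False
            for damp in (1.0, 0.5, 0.25, 0.1):
                cand = params - damp * step
                fcand = neg(cand)
                if fcand <= fval:
                    params, fval, improved = cand, fcand, True
                    break
            if not improved:
                break
            H = approx_hess(params, neg)
        return params, fval, H


def _robust_inverse(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        if np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0):
            return cov
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(H, hermitian=True)


class CopulaJointResults:
    """MLE results: estimates, observed-information covariance, Wald tests."""

    def __init__(self, model, params, llf, cov_params_, converged):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self._cov = np.asarray(cov_params_, dtype=float)
        self.converged = converged

    def cov_params(self) -> np.ndarray:
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        d = np.diag(self._cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.tvalues))

    @property
    def copula_params(self) -> CopulaParams:
        k = self.model.k_exog
        return CopulaParams(
            float(np.exp(self.params[2 * k + 2])),
            1.0 + float(np.exp(self.params[2 * k + 3])),
        )

    @property
    def kendall_tau(self) -> float:
        return bb1_tau(self.copula_params)

    def margin_params(self, margin: int):
        """(coefficients, sigma) of margin 1 (log SAT) or 2 (ratio)."""
        k = self.model.k_exog
        off = 0 if margin == 1 else k + 1
        return self.params[off : off + k], float(np.exp(self.params[off + k]))

    def wald_test_coef(self, name: str, margin: int):
        """(estimate, se, two-sided normal p) for one design column."""
        k = self.model.k_exog
        j = self.model.exog_names.index(name) + (0 if margin == 1 else k + 1)
        return self.params[j], self.bse[j], self.pvalues[j]

    def score_norm(self) -> float:
        """Max |gradient| of the log-likelihood at the optimum."""
        g = approx_fprime(self.params, self.model.loglike, centered=True)
        return float(np.max(np.abs(g)))

    def plot_pit(self, ax=None):
        """Scatter of the probability-integral-transformed residual pair.

        Under a well-specified model the points are a sample from the fitted
        BB1 copula; the overlaid contours show its density.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        g1, s1 = self.margin_params(1)
        g2, s2 = self.margin_params(2)
        u1 = ndtr((self.model.y1 - self.model.exog @ g1) / s1)
        u2 = ndtr((self.model.y2 - self.model.exog @ g2) / s2)
        ax.scatter(u1, u2, s=8, alpha=0.5, color="0.3")
        grid = np.linspace(0.02, 0.98, 60)
        U1, U2 = np.meshgrid(grid, grid)
        dens = np.exp(
            bb1_logdensity(U1, U2, (self.copula_params.phi, self.copula_params.theta))
        )
        ax.contour(U1, U2, dens, levels=6, colors="C0", linewidths=0.8)
        ax.set_xlabel("PIT residual, log SAT margin")
        ax.set_ylabel("PIT residual, SAT/TAT margin")
        ax.set_title(f"fitted BB1, Kendall tau = {self.kendall_tau:.2f}")
        return ax

    def summary(self) -> str:
        names = self.model.param_names()
        lines = [
            "BB1 copula joint regression (Gaussian margins)",
            f"n = {self.model.nobs}, loglik = {self.llf:.3f}, "
            f"converged = {self.converged}",
            f"copula: phi = {self.copula_params.phi:.4f}, "
            f"theta = {self.copula_params.theta:.4f}, "
            f"Kendall tau = {self.kendall_tau:.4f}",
            f"{'parameter':<28}{'estimate':>12}{'std err':>12}{'z':>9}{'P>|z|':>10}",
        ]
        for nm, est, se, z, p in zip(
            names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(f"{nm:<28}{est:>12.4f}{se:>12.4f}{z:>9.2f}{p:>10.2g}")
        return "\n".join(lines)


def joint_loglik(y1, y2, X, params) -> float:
    """Joint copula log-likelihood at an explicit parameter vector."""
    return CopulaJointModel(y1, y2, X).loglike(params)


def fit_copula_model(y1, y2, X, exog_names=None) -> CopulaJointResults:
    """Fit the joint model; convenience wrapper over :class:`CopulaJointModel`."""
    return CopulaJointModel(y1, y2, X, exog_names=exog_names).fit()


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


# ---------------------------------------------------------------------------
# per-gene screens


def _screen_inputs(cohort, covariate_columns=None, pre_transformed=False):
    ph = transform_phenotypes(cohort.phenotypes)
    X0, names = build_design(cohort.covariates, columns=covariate_columns)
    expr = cohort.expression
    return ph["log_sat"].to_numpy(), ph["ratio"].to_numpy(), X0, names, expr


def transcriptome_screen(
    cohort,
    alpha: float = 0.05,
    covariate_columns=None,
    pre_transformed: bool = False,
    n_tests: int | None = None,
):
    """Per-gene joint copula Wald screen over both outcomes.

    Each gene's expression row is Yeo-Johnson transformed (unless
    ``pre_transformed``) and appended to the covariate design; the joint model
    is fitted by MLE and the two expression coefficients are Wald-tested.
    Genes whose expression is constant are skipped but stay in the Bonferroni
    denominator, as do non-converged fits (reported with NaN p-values).

    Returns ``(results, summary)`` where ``results`` has one row per gene
    (beta/se/p for log SAT; beta2/se2/p2 for SAT/TAT; significance flags) and
    ``summary`` carries the 2x2 overlap counts and the Bonferroni cutoff.
    """
    y1, y2, X0, names, expr = _screen_inputs(cohort, covariate_columns)
    G = len(expr.index) if n_tests is None else n_tests
    cutoff = bonferroni_cutoff(alpha, G) if G else np.nan
    rows = []
    for gene in expr.index:
        g = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(g) == 0:
            logger.info("gene %s has constant expression; skipped", gene)
            rows.append((gene, *[np.nan] * 6, False, False, False))
            continue
        if not pre_transformed:
            g, _ = yeo_johnson(g)
        X = np.column_stack([X0, g])
        res = CopulaJointModel(y1, y2, X, exog_names=names + ["expr"]).fit()
        if res.converged:
            b1, se1, p1 = res.wald_test_coef("expr", 1)
            b2, se2, p2 = res.wald_test_coef("expr", 2)
        else:
            b1 = se1 = p1 = b2 = se2 = p2 = np.nan
        rows.append(
            (
                gene,
                b1,
                se1,
                p1,
                b2,
                se2,
                p2,
                bool(p1 < cutoff) if np.isfinite(p1) else False,
                bool(p2 < cutoff) if np.isfinite(p2) else False,
                res.converged,
            )
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "beta",
            "se",
            "p",
            "beta2",
            "se2",
            "p2",
            "significant_sat",
            "significant_ratio",
            "converged",
        ],
    ).set_index("gene_id")
    summary = overlap_counts(results)
    summary.update({"alpha": alpha, "n_tests": G, "cutoff": cutoff})
    return results, summary


def linear_screen(cohort, alpha=0.05, covariate_columns=None, pre_transformed=False,
                  n_tests=None):
    """Sensitivity screen: ordinary least squares per gene per outcome.

    Fits the same marginal models by OLS and t-tests the expression
    coefficient (two-sided, n - k degrees of freedom), with the same
    Bonferroni flagging as the copula screen.
    """
    y1, y2, X0, names, expr = _screen_inputs(cohort, covariate_columns)
    G = len(expr.index) if n_tests is None else n_tests
    cutoff = bonferroni_cutoff(alpha, G) if G else np.nan
    rows = []
    for gene in expr.index:
        g = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(g) == 0:
            rows.append((gene, *[np.nan] * 6, False, False))
            continue
        if not pre_transformed:
            g, _ = yeo_johnson(g)
        X = np.column_stack([X0, g])
        stats = [_ols_last_coef(y, X) for y in (y1, y2)]
        (b1, se1, p1), (b2, se2, p2) = stats
        rows.append(
            (gene, b1, se1, p1, b2, se2, p2, bool(p1 < cutoff), bool(p2 < cutoff))
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "beta",
            "se",
            "p",
            "beta2",
            "se2",
            "p2",
            "significant_sat",
            "significant_ratio",
        ],
    ).set_index("gene_id")
    summary = overlap_counts(results)
    summary.update({"alpha": alpha, "n_tests": G, "cutoff": cutoff})
    return results, summary


def _ols_last_coef(y, X):
    """(coef, se, two-sided t p-value) for the last column of X."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design in linear screen")
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ (X.T @ y)
    resid = y - X @ b
    s2 = resid @ resid / (n - k)
    se = np.sqrt(s2 * XtX_inv[-1, -1])
    tval = b[-1] / se
    p = 2.0 * t_dist.sf(abs(tval), n - k)
    return b[-1], se, p


def overlap_counts(results: pd.DataFrame) -> dict:
    """Table-2-style counts: SAT-only, ratio-only, both, total."""
    s = results["significant_sat"].astype(bool)
    r = results["significant_ratio"].astype(bool)
    both = int((s & r).sum())
    return {
        "sat_only": int((s & ~r).sum()),
        "ratio_only": int((~s & r).sum()),
        "both": both,
        "total": int((s | r).sum()),
        "n_sat": int(s.sum()),
        "n_ratio": int(r.sum()),
    }
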