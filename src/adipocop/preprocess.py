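"""Normalization and variable transformations.

The expression pipeline is TPM -> TMM -> low-expression filter ->
per-gene Yeo-Johnson; the outcomes are log SAT (natural log) and the raw,
untransformed SAT/TAT ratio.

The TMM step here scales an already within-sample-normalized matrix (TPM),
so M-values are plain log2 ratios between a sample and the reference column
without a library-size offset; trimming (30% of M, 5% of A, each tail) and
inverse-variance weighting follow the Robinson-Oshlack construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import yeojohnson, yeojohnson_llf

__all__ = [
    "NormalizationResult",
    "tpm",
    "tmm_factors",
    "filter_low_expressed",
    "yeo_johnson",
    "transform_phenotypes",
    "normalize_expression",
]


@dataclass
class NormalizationResult:
    """Output of the expression normalization pipeline."""

    tpm: pd.DataFrame
    tmm_factors: pd.Series
    kept_genes: pd.Index
    yj_lambda: pd.Series
    normalized: pd.DataFrame  # TMM-scaled TPM restricted to kept genes
    transformed: pd.DataFrame  # Yeo-Johnson transform of `normalized`


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and effective gene lengths.

    ``rate = count / length`` per gene; each sample's rates are rescaled to
    sum to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total rate in sample(s): {zero.index.tolist()}")
    return rate.div(totals, axis=1) * 1e6


def _tmm_reference(x: np.ndarray) -> int:
    uq = np.percentile(x, 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    values: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    The reference is the sample whose upper quartile is closest to the mean
    upper quartile.  For each sample, genes expressed in both the sample and
    the reference contribute M = log2(x_s/x_r) and A = 0.5*log2(x_s*x_r);
    both tails of M (``logratio_trim``) and of A (``sum_trim``) are trimmed
    and the factor is 2**(weighted mean M), weighted by inverse delta-method
    variances.  Factors are rescaled to geometric mean 1.
    """
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    ref = _tmm_reference(X)
    xr = X[:, ref]
    totals = X.sum(axis=0)
    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        xs = X[:, j]
        both = (xs > 0) & (xr > 0)
        if not both.any():
            raise ValueError(
                f"sample {values.columns[j]!r} shares no expressed gene with the reference"
            )
        ps, pr = xs[both] / totals[j], xr[both] / totals[ref]
        m = np.log2(xs[both] / xr[both])
        a = 0.5 * np.log2(xs[both] * xr[both])
        # doubly trimmed: keep central mass of both M and A
        n = m.size
        rm = pd.Series(m).rank(method="first").to_numpy()
        ra = pd.Series(a).rank(method="first").to_numpy()
        keep = (
            (rm >= np.floor(n * logratio_trim) + 1)
            & (rm <= n - np.floor(n * logratio_trim))
            & (ra >= np.floor(n * sum_trim) + 1)
            & (ra <= n - np.floor(n * sum_trim))
        )
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        # asymptotic (binomial) variance of M
        w = 1.0 / ((1 - ps) / (totals[j] * ps) + (1 - pr) / (totals[ref] * pr))
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


def filter_low_expressed(expr: pd.DataFrame, min_fraction: float = 0.25) -> pd.Index:
    """Gene ids expressed (value > 0) in at least ``min_fraction`` of samples."""
    frac = (expr > 0).mean(axis=1)
    return expr.index[frac >= min_fraction]


def yeo_johnson(x, lmbda: float | None = None):
    """Yeo-Johnson power transform; lambda by profile ML if not given.

    The profile Gaussian log-likelihood is maximized over lambda in [-5, 5]
    by bounded golden-section/Brent search (tolerance 1e-6).  Constant input
    is returned unchanged with lambda = 1 and a warning.

    Returns ``(transformed, lmbda)``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if lmbda is None:
        if np.ptp(x) == 0:
            warnings.warn("constant input; Yeo-Johnson skipped (lambda=1)", stacklevel=2)
            return x.copy(), 1.0
        res = minimize_scalar(
            lambda lm: -yeojohnson_llf(lm, x),
            bounds=(-5.0, 5.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lmbda = float(res.x)
    return yeojohnson(x, lmbda=lmbda), float(lmbda)


def transform_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Analysis-scale outcomes: (log SAT, SAT/TAT).

    SAT is natural-log transformed; the ratio is left untransformed.
    """
    sat = phenotypes["SAT"]
    tat = phenotypes["TAT"]
    if (sat <= 0).any():
        raise ValueError("SAT must be positive for the log transform")
    return pd.DataFrame({"log_sat": np.log(sat), "ratio": sat / tat})


def normalize_expression(
    counts: pd.DataFrame,
    lengths: pd.Series | None = None,
    min_fraction: float = 0.25,
) -> NormalizationResult:
    """Full expression pipeline: TPM -> TMM -> filter -> Yeo-Johnson.

    If ``lengths`` is None the input is treated as already length-normalized
    (unit lengths), which is how the synthetic generator's matrices enter.
    """
    if lengths is None:
        lengths = pd.Series(1.0, index=counts.index)
    t = tpm(counts, lengths)
    f = tmm_factors(t)
    scaled = t.div(f, axis=1)
    kept = filter_low_expressed(scaled, min_fraction=min_fraction)
    scaled = scaled.loc[kept]
    trans = np.empty(scaled.shape)
    lambdas = np.empty(len(kept))
    for i in range(len(kept)):
        trans[i], lambdas[i] = yeo_johnson(scaled.iloc[i].to_numpy())
    return NormalizationResult(
        tpm=t,
        tmm_factors=f,
        kept_genes=kept,
        yj_lambda=pd.Series(lambdas, index=kept, name="yj_lambda"),
        normalized=scaled,
        transformed=pd.DataFrame(trans, index=kept, columns=scaled.columns),
    )
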