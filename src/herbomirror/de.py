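"""Per-gene linear-model contrasts with empirical-Bayes moderation.

Each gene's log2 expression across arrays is fitted by ordinary least
squares against a shared design matrix; a contrast (a weight vector over
coefficients) yields a per-gene log2 fold-change estimate. The gene-wise
residual variances s_g^2 are then shrunk toward a common prior: assuming
s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_df / df and 1/sigma_g^2 ~
chi^2_d0 / (d0 s0^2), the posterior variance is

    s~_g^2 = (d0 s0^2 + df s_g^2) / (d0 + df)

and the moderated t = beta_g / (se_unscaled * s~_g) has d0 + df degrees
of freedom. The hyperparameters (d0, s0^2) are estimated by matching
moments of log s_g^2 against the scaled-F prior predictive (digamma /
trigamma inversion). Family-wise error is controlled by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import polygamma

from .exprproc import ExpressionMatrix

__all__ = [
    "DesignMatrix",
    "ContrastSpec",
    "FitResult",
    "ModeratedStats",
    "fit_lm",
    "ebayes_moderate",
    "bonferroni_select",
    "contrast_set_difference",
    "trigamma_inverse",
    "design_from_conditions",
]


@dataclass
class DesignMatrix:
    """Arrays x coefficients model matrix with named coefficients."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be arrays x len(names)")


@dataclass
class ContrastSpec:
    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights != 0):
            raise ValueError("contrast weights must not all be zero")


@dataclass
class FitResult:
    gene_ids: list[str]
    coefficients: np.ndarray  # genes x coefficients
    contrast_name: str
    estimate: np.ndarray  # genes, log2 scale
    se_unscaled: float  # sqrt(w' (X'X)^-1 w), shared across genes
    s2: np.ndarray  # genes, residual variance
    df: int


@dataclass
class ModeratedStats:
    gene_ids: list[str]
    estimate: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_bonf: np.ndarray
    s2_post: np.ndarray
    d0: float  # prior df; may be inf
    s02: float  # prior variance
    df_total: float


def design_from_conditions(
    conditions: Sequence[str], baseline: str | None = None
) -> DesignMatrix:
    """Treatment-coded design: intercept (baseline) + one indicator per level."""
    levels: list[str] = []
    for c in conditions:
        if c not in levels:
            levels.append(c)
    if baseline is None:
        baseline = levels[0]
    if baseline not in levels:
        raise ValueError(f"baseline {baseline!r} not among conditions")
    others = [l for l in levels if l != baseline]
    mat = np.zeros((len(conditions), 1 + len(others)))
    mat[:, 0] = 1.0
    for j, lvl in enumerate(others):
        mat[:, 1 + j] = [1.0 if c == lvl else 0.0 for c in conditions]
    return DesignMatrix(mat, ["(intercept)"] + others)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name columns whose removal restores full rank."""
    rank = np.linalg.matrix_rank(x)
    bad = []
    for j in range(x.shape[1]):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(names[j])
    return bad


def fit_lm(e: ExpressionMatrix, d: DesignMatrix, c: ContrastSpec) -> FitResult:
    """Gene-wise ordinary least squares and contrast extraction."""
    x = d.matrix
    n, p = x.shape
    if n != len(e.array_ids):
        raise ValueError("design rows must match expression arrays")
    if c.weights.size != p:
        raise ValueError("contrast length must match design coefficients")
    if np.linalg.matrix_rank(x) < p:
        bad = _collinear_columns(x, d.names)
        raise ValueError(f"design matrix is rank deficient (collinear: {bad})")
    if n <= p:
        raise ValueError("residual degrees of freedom must be positive")
    xtx_inv = np.linalg.inv(x.T @ x)
    # coef = Y X (X'X)^-1, Y genes x arrays
    coef = e.values @ x @ xtx_inv
    resid = e.values - coef @ x.T
    df = n - p
    s2 = np.sum(resid**2, axis=1) / df
    estimate = coef @ c.weights
    se_unscaled = float(np.sqrt(c.weights @ xtx_inv @ c.weights))
    return FitResult(
        gene_ids=list(e.probeset_ids),
        coefficients=coef,
        contrast_name=c.name,
        estimate=estimate,
        se_unscaled=se_unscaled,
        s2=s2,
        df=df,
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log residual variances.

    If s^2 ~ s0^2 F(df, d0), then e = log s^2 - digamma(df/2) + log(df/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2). Zero variances carry no information
    about the scale and are excluded; a nonpositive moment estimate of
    trigamma(d0/2) means the spread of variances is no larger than chi^2
    sampling alone explains, and the limit d0 = inf (all genes share one
    variance s0^2) is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        return np.inf, 0.0
    e = np.log(pos) - float(polygamma(0, df / 2.0)) + np.log(df / 2.0)
    emean = float(e.mean())
    # d0 = inf limit: the prior is a point mass, so the observed variances
    # are taken at face value (geometric mean, no chi-square log-bias term)
    if pos.size < 2:
        return np.inf, float(np.exp(np.mean(np.log(pos))))
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(np.log(pos))))
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = float(np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def ebayes_moderate(f: FitResult, d0: float | None = None, s02: float | None = None) -> ModeratedStats:
    """Empirical-Bayes variance moderation and moderated t statistics.

    Hyperparameters are estimated from all genes unless supplied (d0=0
    forces ordinary t; d0=inf pools all variances at s0^2). Degenerate
    genes with zero posterior variance get t = 0, p = 1 when the estimate
    is also zero, else |t| = inf, p = 0.
    """
    if d0 is None or s02 is None:
        d0_est, s02_est = estimate_prior(f.s2, f.df)
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02
    if np.isinf(d0):
        s2_post = np.full_like(f.s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = f.s2.copy()
        df_total = float(f.df)
    else:
        s2_post = (d0 * s02 + f.df * f.s2) / (d0 + f.df)
        df_total = d0 + f.df
    denom = f.se_unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, f.estimate / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.where((denom == 0) & (f.estimate != 0), np.sign(f.estimate) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((denom == 0) & (f.estimate == 0), 1.0, p)
    p = np.where(np.isinf(t), 0.0, p)
    return ModeratedStats(
        gene_ids=f.gene_ids,
        estimate=f.estimate,
        t=t,
        p=p,
        p_bonf=np.minimum(1.0, p * len(f.gene_ids)),
        s2_post=s2_post,
        d0=float(d0),
        s02=float(s02),
        df_total=float(df_total),
    )


def bonferroni_select(
    stats_: ModeratedStats, alpha: float = 0.05, m: int | None = None
) -> tuple[list[str], np.ndarray]:
    """Genes whose Bonferroni-adjusted p-value is strictly below alpha.

    ``m`` defaults to the number of genes actually tested (post-filtering
    row count), not the chip size. Returns (selected ids in input order,
    adjusted p for all genes).
    """
    if m is None:
        m = len(stats_.gene_ids)
    adjusted = np.minimum(1.0, stats_.p * m)
    selected = [g for g, a in zip(stats_.gene_ids, adjusted) if a < alpha]
    return selected, adjusted


def contrast_set_difference(list_a: Sequence[str], list_b: Sequence[str]) -> list[str]:
    """Ids present in ``list_a`` but not ``list_b``, preserving a's order."""
    b = set(list_b)
    return [g for g in list_a if g not in b]
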