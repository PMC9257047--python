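"""Elementary statistics implemented from first principles.

Every downstream stage of the pair-signature pipeline rests on four
primitives: product-moment correlation (Pearson, and Spearman as Pearson on
mid-ranks), the two-sample Mann-Whitney rank-sum test, the empirical-Bayes
moderated t-statistic for two-group differential expression, and
Benjamini-Hochberg step-up adjustment.  They are implemented here directly
from their definitions; scipy supplies only distribution functions
(Student t, normal) and the digamma/trigamma special functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as _spdist

__all__ = [
    "CorrelationResult",
    "TestResult",
    "ConstantInputError",
    "pearson",
    "spearman",
    "rank_test",
    "moderated_t_table",
    "bh_adjust",
    "midranks",
]

_TINY_P = np.finfo(float).tiny  # smallest reported p-value


class ConstantInputError(ValueError):
    """A correlation or test is undefined because an input is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation coefficient with its two-sided p-value."""

    r: float
    n: int
    p: float
    method: Literal["pearson", "spearman"]


@dataclass(frozen=True)
class TestResult:
    """Two-sample location test result.

    ``direction`` is the sign of the location shift of group 1 relative to
    group 2 (+1 when group 1 sits higher in the pooled ranking).
    """

    statistic: float
    p: float
    n1: int
    n2: int
    direction: int


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D value vector")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in input vector")
    return a


def _corr_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via t = r*sqrt((n-2)/(1-r^2))."""
    if abs(r) >= 1.0:
        return _TINY_P
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _spdist.t.sf(abs(t), df=n - 2)
    return max(float(p), _TINY_P)


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a Student-t p-value.

    Requires equal-length vectors of length >= 3; raises
    :class:`ConstantInputError` when either vector is constant (the
    correlation is then undefined and callers treat the pair as
    non-correlated).
    """
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size:
        raise ValueError("x and y must have the same length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = np.sqrt(np.sum(xd * xd))
    sy = np.sqrt(np.sum(yd * yd))
    if sx == 0.0 or sy == 0.0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    return CorrelationResult(r=r, n=n, p=_corr_p(r, n), method="pearson")


def midranks(x) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    a = np.asarray(x, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sorted_a = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks, same t transform."""
    xa, ya = _as_1d(x), _as_1d(y)
    if xa.size != ya.size:
        raise ValueError("x and y must have the same length")
    try:
        res = pearson(midranks(xa), midranks(ya))
    except ConstantInputError:
        raise ConstantInputError(
            "rank correlation undefined: a vector is constant after ranking"
        ) from None
    return CorrelationResult(r=res.r, n=res.n, p=res.p, method="spearman")


def _exact_u_pvalue(u: float, n1: int, n2: int) -> float:
    """Exact two-sided Mann-Whitney p by enumeration of rank assignments.

    Valid only without ties.  Two-sided p = P(|U - n1*n2/2| >= |u - n1*n2/2|)
    under the uniform null over all C(n1+n2, n1) assignments.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    obs_dev = abs(u - mu)
    hits = 0
    total = 0
    base = n1 * (n1 + 1) // 2
    for ranks in combinations(range(1, n + 1), n1):
        u_perm = sum(ranks) - base
        total += 1
        if abs(u_perm - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def rank_test(a, b, exact_threshold: int = 12) -> TestResult:
    """Two-sample Mann-Whitney rank-sum test with mid-ranks.

    Exact two-sided p by full enumeration when ``n1 + n2 <= exact_threshold``
    and there are no ties; otherwise the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    aa, ba = _as_1d(a), _as_1d(b)
    n1, n2 = aa.size, ba.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([aa, ba])
    ranks = midranks(pooled)
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if n1 + n2 <= exact_threshold and not has_ties:
        p = _exact_u_pvalue(u, n1, n2)
    else:
        n = n1 + n2
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0  # everything tied: no evidence either way
        else:
            dev = abs(u - mu)
            z = max(dev - 0.5, 0.0) / np.sqrt(var)
            p = 2.0 * _spdist.norm.sf(z)
    p = float(min(1.0, max(p, _TINY_P)))
    direction = int(np.sign(u - mu))
    return TestResult(statistic=u, p=p, n1=n1, n2=n2, direction=direction)


def _trigamma_inverse(v: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = v for x > 0 by Newton iteration."""
    if v <= 0:
        return np.inf
    # trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / v
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        tet = special.polygamma(2, x)
        step = (tri - v) / tet
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return float(x_new)
        x = x_new
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the inverse-chi-square variance prior.

    Matches the first two moments of log(s^2) for scaled chi-square sampling
    variation around a common prior (d0, s0^2).  Genes with zero sample
    variance are excluded from the fit.  Returns (d0, s0sq); d0 may be inf,
    meaning all posterior variances equal s0sq.
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(excess) or excess <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(excess)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(ebar))
    s0sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_t_table(
    expr: pd.DataFrame,
    groups: pd.Series,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group differential expression with empirical-Bayes moderated t.

    Parameters
    ----------
    expr
        Genes x samples matrix of log2 expression.
    groups
        Label per sample (index-aligned with ``expr`` columns), values
        ``"tumor"`` / ``"normal"``.
    prior_df
        Override for the prior degrees of freedom d0.  ``0`` gives the
        ordinary pooled-variance t; ``inf`` shrinks every gene variance to
        the prior; ``None`` (default) fits (d0, s0^2) by method of moments
        on the log sample variances.

    Returns
    -------
    DataFrame indexed by gene with columns ``logFC`` (tumor - normal mean),
    ``t`` (moderated t), ``p``, ``fdr`` (BH) and ``direction`` (up/down).
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("every expression sample needs a tumor/normal label")
    tumor = expr.loc[:, (groups == "tumor").to_numpy()]
    normal = expr.loc[:, (groups == "normal").to_numpy()]
    n1, n2 = tumor.shape[1], normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")

    m1 = tumor.mean(axis=1).to_numpy()
    m2 = normal.mean(axis=1).to_numpy()
    logfc = m1 - m2
    df_resid = n1 + n2 - 2
    ss = tumor.sub(tumor.mean(axis=1), axis=0).pow(2).sum(axis=1) + normal.sub(
        normal.mean(axis=1), axis=0
    ).pow(2).sum(axis=1)
    s2 = (ss / df_resid).to_numpy()

    if prior_df is None:
        d0, s0sq = _fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0sq = _fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * _spdist.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * _spdist.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, _TINY_P, 1.0)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t_mod,
            "p": p,
            "fdr": bh_adjust(p),
            "direction": np.where(logfc >= 0, "up", "down"),
        },
        index=expr.index,
    )
    out.index.name = "gene_id"
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pa = np.asarray(p, dtype=float)
    if pa.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if pa.size == 0:
        return pa.copy()
    if np.any((pa < 0) | (pa > 1) | ~np.isfinite(pa)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pa.size
    order = np.argsort(pa, kind="mergesort")
    adj_sorted = pa[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj
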