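"""Heteroscedasticity-aware statistical toolkit for skill assessment.

Implements, from their ANOVA-decomposition formulas: Levene's
variance-homogeneity test (mean- or median-centered), Welch's ANOVA
with Satterthwaite-type degrees of freedom, the Games-Howell post-hoc
(pairwise Welch statistics referred to the studentized-range
distribution), Spearman rank correlation with a permutation-null
critical value, and the intraclass correlation ICC(2,1) (two-way
random effects, single measures, absolute agreement).

Grouped inputs are mappings {group label: 1-D samples}; ties in the
rank statistics are handled by midranks throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LeveneResult",
    "WelchAnovaResult",
    "SpearmanResult",
    "ICCResult",
    "levene_test",
    "welch_anova",
    "games_howell",
    "spearman_with_critical",
    "icc_2_1",
]


def _groups_to_arrays(groups) -> tuple[list, list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float).ravel() for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
        labels = list(range(len(arrays)))
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for lab, a in zip(labels, arrays):
        if a.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {lab!r} contains non-finite values")
    return labels, arrays


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    pvalue: float
    df1: int
    df2: int
    center: str


def levene_test(groups, center: str = "mean") -> LeveneResult:
    """Levene's W for equality of variances across groups.

    A one-way ANOVA on the absolute deviations Z_ij = |x_ij - c_i| from
    the group center c_i (mean by default; ``center="median"`` gives the
    Brown-Forsythe variant). W is referred to F(K-1, N-K).
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    _, arrays = _groups_to_arrays(groups)
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    centers = [a.mean() if center == "mean" else np.median(a) for a in arrays]
    Z = [np.abs(a - c) for a, c in zip(arrays, centers)]
    k = len(Z)
    n = np.array([z.size for z in Z])
    N = int(n.sum())
    zbar_i = np.array([z.mean() for z in Z])
    zbar = np.concatenate(Z).mean()
    num = (N - k) * np.sum(n * (zbar_i - zbar) ** 2)
    den = (k - 1) * sum(np.sum((z - zi) ** 2) for z, zi in zip(Z, zbar_i))
    if den == 0:
        # all deviations equal within groups: no evidence of heteroscedasticity
        return LeveneResult(0.0, 1.0, k - 1, N - k, center)
    W = num / den
    p = float(sps.f.sf(W, k - 1, N - k))
    return LeveneResult(float(W), p, k - 1, N - k, center)


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    pvalue: float


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Groups are weighted by w_i = n_i / s_i^2; the F statistic uses
    Satterthwaite-type denominator degrees of freedom, so unequal
    variances do not inflate the type-I error the way classic ANOVA's
    pooled variance does.
    """
    _, arrays = _groups_to_arrays(groups)
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    s2 = np.array([a.var(ddof=1) for a in arrays])
    if np.all(s2 == 0):
        raise ValueError("all groups have zero within-group variance")
    s2 = np.where(s2 == 0, np.finfo(float).tiny, s2)
    w = n / s2
    sw = w.sum()
    mw = np.sum(w * m) / sw
    a_term = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / sw) ** 2 / (n - 1))
    b_term = 1 + 2 * (k - 2) / (k * k - 1) * lam
    F = a_term / b_term
    df1 = k - 1.0
    df2 = (k * k - 1) / (3 * lam) if lam > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    return WelchAnovaResult(float(F), df1, float(df2), p)


def games_howell(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell pairwise post-hoc comparisons.

    For each pair the Welch-type statistic
    t = (m_i - m_j) / sqrt(s_i^2/n_i + s_j^2/n_j) is referred to the
    studentized-range distribution with k groups and Welch-Satterthwaite
    degrees of freedom (p = P(q >= t*sqrt(2))), which controls the
    family-wise error rate at ``alpha`` under unequal variances.
    Singleton groups cannot contribute a variance and their pairs are
    skipped with a warning.

    Returns a tidy frame: group_a, group_b, mean_diff, t, df, pvalue,
    significant.
    """
    import warnings

    labels, arrays = _groups_to_arrays(groups)
    k = len(arrays)
    rows = []
    for (la, a), (lb, b) in itertools.combinations(zip(labels, arrays), 2):
        if a.size < 2 or b.size < 2:
            warnings.warn(
                f"skipping pair ({la!r}, {lb!r}): singleton group", RuntimeWarning
            )
            continue
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se2 = va + vb
        if se2 == 0:
            t = 0.0
            df = a.size + b.size - 2.0
        else:
            t = float(np.abs(a.mean() - b.mean()) / np.sqrt(se2))
            df = float(se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))
        p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "mean_diff": float(a.mean() - b.mean()),
                "t": t,
                "df": df,
                "pvalue": min(1.0, p),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    critical_value: float
    significant: bool
    n: int
    n_perm: int
    alpha: float


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_with_critical(
    x,
    y,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SpearmanResult:
    """Spearman rho with a one-sided permutation-null critical value.

    rho is the Pearson correlation of midranks. The critical value is
    the empirical (1 - alpha) quantile of rho over ``n_perm`` random
    permutations of y (one-tailed; the tabulated 0.446 for N = 15 at
    alpha = 0.05 corresponds to two-tailed 0.10). ``significant`` is
    rho > critical value.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman's rho is undefined for a constant input")
    rx, ry = _rank(x), _rank(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    n = x.size
    rho = float(np.mean(zx * zy))

    rng = np.random.default_rng(seed)
    # permuting the standardized ranks of y preserves the tie pattern
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    null_rho = (zy[perm] @ zx) / n
    crit = float(np.quantile(null_rho, 1.0 - alpha))
    return SpearmanResult(rho, crit, rho > crit, n, n_perm, alpha)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    anova: dict  # MSR, MSC, MSE and the sums of squares, for auditability
    n: int
    k: int


def icc_2_1(table) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``table`` is an n x k matrix (rows = rated targets, columns = raters)
    with no missing cells. From the two-way ANOVA decomposition with
    mean squares MSR (rows), MSC (columns) and MSE (residual):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)
    """
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy()
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("rater table must be at least 2 targets x 2 raters")
    if not np.all(np.isfinite(X)):
        raise ValueError("rater table must be complete (no missing cells)")
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_total = np.sum((X - grand) ** 2)
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(
        icc=float(icc),
        anova={
            "MSR": float(msr),
            "MSC": float(msc),
            "MSE": float(mse),
            "SS_rows": float(ss_rows),
            "SS_cols": float(ss_cols),
            "SS_error": float(ss_err),
        },
        n=n,
        k=k,
    )
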