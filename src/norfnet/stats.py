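"""Shared exact statistics.

Small wrappers with fixed conventions so that every module reports
association tests, effect sizes and multiple-testing corrections the same
way: Fisher's exact test (probability-mass two-sided rule) with a sample
odds ratio and Woolf-logit confidence interval, Benjamini-Hochberg step-up
FDR, Cliff's delta, and the Mann-Whitney U test with exact small-sample
p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "fisher_exact",
    "bh_adjust",
    "cliffs_delta",
    "mann_whitney",
]

#: smallest p-value ever reported; p = 0 is never returned
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class StatResult:
    """A named test statistic with its p-value and optional 95% CI."""

    name: str
    value: float
    p: float
    ci_low: float | None = None
    ci_high: float | None = None


def fisher_exact(table, sided: str = "two-sided") -> StatResult:
    """Fisher's exact test on a 2x2 contingency table.

    Parameters
    ----------
    table
        2x2 array of nonnegative integer counts ``[[a, b], [c, d]]``.
    sided
        ``"two-sided"`` (sum of tables with probability <= observed),
        ``"greater"`` or ``"less"`` (one-sided on the odds ratio of the
        first row).

    Returns
    -------
    StatResult with the sample odds ratio ``ad/bc`` and a Woolf-logit 95%
    confidence interval (0.5 added to every cell when any cell is zero).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 array of nonnegative integers")
    a, b, c, d = t.ravel()
    # degenerate margins: no information
    if min(a + b, c + d, a + c, b + d) == 0:
        return StatResult("odds_ratio", float("nan"), 1.0)
    if sided not in {"two-sided", "less", "greater"}:
        raise ValueError(f"unknown alternative {sided!r}")
    _, p = sps.fisher_exact(t, alternative=sided)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    # Woolf-logit CI; Haldane-Anscombe 0.5 correction when a cell is empty
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    log_or = math.log((a2 * d2) / (b2 * c2))
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo, hi = math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)
    return StatResult("odds_ratio", odds, max(float(p), P_FLOOR), lo, hi)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size: P(x > y) - P(x < y), ties count zero.

    Computed from the Mann-Whitney U statistic, d = 2 U_x / (n_x n_y) - 1,
    which is exactly the pairwise win-loss difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires two nonempty samples")
    # U_x counts wins + half the ties of x over y
    u_x = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").statistic
    return float(2.0 * u_x / (x.size * y.size) - 1.0)


def _exact_mwu_with_ties(x: np.ndarray, y: np.ndarray, sided: str) -> float:
    """Exact Mann-Whitney p by full enumeration of group assignments.

    Valid with ties (midranks); only used when C(n+m, n) is small.
    """
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    total = 0
    count_ge = 0
    count_le = 0
    count_extreme = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        total += 1
        if u >= u_obs - 1e-9:
            count_ge += 1
        if u <= u_obs + 1e-9:
            count_le += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count_extreme += 1
    if sided == "greater":
        return count_ge / total
    if sided == "less":
        return count_le / total
    return min(1.0, count_extreme / total)


def mann_whitney(x, y, sided: str = "two-sided") -> StatResult:
    """Mann-Whitney U test (midranks for ties).

    Uses the exact null distribution for small samples (n_x * n_y <= 400):
    scipy's tie-free recursion when there are no ties, full enumeration of
    the C(n+m, n) group assignments when ties are present and enumeration
    is tractable. Otherwise the normal approximation with tie and
    continuity corrections. The reported statistic is U for the first
    sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two nonempty samples")
    alt = sided if sided != "two-sided" else "two-sided"
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = x.size * y.size <= 400
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative=alt, method="exact")
        p = float(res.pvalue)
        u = float(res.statistic)
    elif small and has_ties and math.comb(x.size + y.size, x.size) <= 200_000:
        u = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").statistic)
        p = _exact_mwu_with_ties(x, y, alt)
    else:
        res = sps.mannwhitneyu(x, y, alternative=alt, method="asymptotic")
        p = float(res.pvalue)
        u = float(res.statistic)
    return StatResult("mann_whitney_u", u, max(min(p, 1.0), P_FLOOR))
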