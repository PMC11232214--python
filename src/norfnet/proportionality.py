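"""Pairwise proportionality on pairwise-complete clr data, spatial quantile
normalization of the resulting coexpression matrix, and edge-threshold
selection.

Proportionality rho for two clr vectors a_x, a_y over the samples where both
ORFs are detected:

    rho = 2 cov(a_x, a_y) / (var(a_x) + var(a_y))
        = 1 - var(a_x - a_y) / (var(a_x) + var(a_y))

rho rewards pairs whose clr values move with equal magnitude, not merely in
the same direction, and lies in [-1, 1]. Pairs with fewer shared detected
samples than ``min_shared`` (or with a zero variance) are reported missing.

The raw rho distribution drifts with expression level (lowly expressed ORF
pairs are biased toward weaker rho), so the matrix is normalized by spatial
quantile normalization: ORFs are grouped into expression strata by mean clr
and the rho distribution of each stratum-pair bin is quantile-mapped onto
the distribution of the highest-expression bin. The map is monotone, so
within-bin rank order is untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ClrMatrix

__all__ = [
    "CoexpressionMatrix", "SpqnConfig", "ThresholdResult",
    "rho_pair", "rho_matrix", "spqn_normalize",
    "percentile_threshold", "coverage_threshold",
]


@dataclass
class CoexpressionMatrix:
    """Symmetric rho matrix with per-pair shared-sample counts."""

    rho: pd.DataFrame                    # NaN where undefined
    n_shared: pd.DataFrame
    min_shared: int = 400
    normalized: bool = False

    @property
    def orf_ids(self):
        return self.rho.index

    def offdiag_values(self) -> np.ndarray:
        """Non-missing off-diagonal rho values (each unordered pair once)."""
        r = self.rho.to_numpy()
        iu = np.triu_indices(r.shape[0], k=1)
        v = r[iu]
        return v[~np.isnan(v)]

    def to_long(self) -> pd.DataFrame:
        r = self.rho.to_numpy()
        n = self.n_shared.to_numpy()
        iu = np.triu_indices(r.shape[0], k=1)
        ids = self.rho.index.to_numpy()
        df = pd.DataFrame({
            "orf1": ids[iu[0]], "orf2": ids[iu[1]],
            "rho": r[iu], "n_shared": n[iu],
        })
        return df.dropna(subset=["rho"]).reset_index(drop=True)


@dataclass
class SpqnConfig:
    n_groups: int = 10
    ref_group: int | None = None         # default: highest-expression group
    n_quantile_points: int = 1000

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")


@dataclass
class ThresholdResult:
    threshold: float
    rule: str                            # "percentile" | "coverage"
    pair_fraction: float = float("nan")  # achieved fraction of pairs kept
    coverage: float = float("nan")       # achieved canonical-ORF coverage

    def passes(self, values) -> np.ndarray:
        """Edge rule: strict ">" for percentile, ">=" for coverage."""
        v = np.asarray(values, dtype=float)
        if self.rule == "percentile":
            return v > self.threshold
        return v >= self.threshold


def rho_pair(a_x, a_y, min_shared: int = 400) -> float:
    """Proportionality of one pair over shared detected samples.

    Returns NaN when fewer than ``min_shared`` samples are shared or either
    vector is constant over the shared samples.
    """
    a_x = np.asarray(a_x, dtype=float)
    a_y = np.asarray(a_y, dtype=float)
    if a_x.shape != a_y.shape:
        raise ValueError("clr vectors must be aligned")
    shared = ~(np.isnan(a_x) | np.isnan(a_y))
    n = int(shared.sum())
    if n < max(min_shared, 2):
        return float("nan")
    x, y = a_x[shared], a_y[shared]
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - 1)
    return float(2.0 * cov / (vx + vy))


def rho_matrix(clr: ClrMatrix, min_shared: int = 400) -> CoexpressionMatrix:
    """All-pairs proportionality with pairwise-complete observations.

    Vectorized via masked cross-products: for each pair the sums of x, y,
    x^2, y^2 and xy are accumulated over the samples where both ORFs are
    detected, giving the shared-sample variances and covariance in a
    handful of matrix products.
    """
    A = clr.values.to_numpy(dtype=float)
    if A.shape[0] < 2:
        raise ValueError("need at least two ORFs")
    M = (~np.isnan(A)).astype(float)
    Z = np.where(np.isnan(A), 0.0, A)
    N = M @ M.T                          # shared detected samples
    Sx = Z @ M.T                         # sum of x over shared samples
    Sy = Sx.T
    Sxx = (Z * Z) @ M.T
    Syy = Sxx.T
    Sxy = Z @ Z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = Sxx - Sx * Sx / N          # sums of squared deviations
        ssy = Syy - Sy * Sy / N
        sxy = Sxy - Sx * Sy / N
        rho = 2.0 * sxy / (ssx + ssy)
    # numerical guard: zero variance on the shared samples -> undefined
    tiny = 1e-12
    rho[(ssx <= tiny) | (ssy <= tiny)] = np.nan
    rho[N < max(min_shared, 2)] = np.nan
    np.clip(rho, -1.0, 1.0, out=rho)
    diag_ok = M.sum(axis=1) >= min_shared
    np.fill_diagonal(rho, np.where(diag_ok, 1.0, np.nan))
    ids = clr.values.index
    return CoexpressionMatrix(
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(N.astype(int), index=ids, columns=ids),
        min_shared=min_shared,
    )


def _quantile_map(values: np.ndarray, ref: np.ndarray, n_points: int
                  ) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_points)
    bq = np.quantile(values, qs)
    rq = np.quantile(ref, qs)
    return np.interp(values, bq, rq)


def spqn_normalize(coex: CoexpressionMatrix, mean_expr: pd.Series,
                   cfg: SpqnConfig | None = None) -> CoexpressionMatrix:
    """Spatial quantile normalization of the coexpression matrix.

    ORFs are ranked by ``mean_expr`` (mean clr) and cut into
    ``cfg.n_groups`` equal-size strata; for every unordered stratum pair
    the non-missing rho values are quantile-mapped (linear interpolation
    between ``n_quantile_points`` empirical quantiles) onto the reference
    bin, by default the highest-expression x highest-expression bin.
    Missing entries stay missing and the matrix stays symmetric because a
    pair's bin is unordered.
    """
    cfg = cfg or SpqnConfig()
    me = mean_expr.reindex(coex.orf_ids)
    if me.isna().any():
        raise ValueError("mean expression missing for some ORFs")
    order = np.argsort(me.to_numpy(), kind="stable")
    groups = np.empty(len(order), dtype=int)
    for g, chunk in enumerate(np.array_split(order, cfg.n_groups)):
        groups[chunk] = g
    ref_g = cfg.ref_group if cfg.ref_group is not None else cfg.n_groups - 1

    R = coex.rho.to_numpy().copy()
    n = R.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    gi, gj = groups[iu], groups[ju]
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    vals = R[iu, ju]
    finite = ~np.isnan(vals)

    ref_sel = finite & (lo == ref_g) & (hi == ref_g)
    ref_vals = vals[ref_sel]
    if ref_vals.size < 2:
        raise ValueError("reference bin has fewer than 2 values")

    out = vals.copy()
    for a in range(cfg.n_groups):
        for b in range(a, cfg.n_groups):
            if (a, b) == (ref_g, ref_g):
                continue
            sel = finite & (lo == a) & (hi == b)
            if sel.sum() < 2:
                if sel.any():
                    warnings.warn(f"SpQN bin ({a},{b}) has <2 values; "
                                  "left unchanged")
                continue
            out[sel] = _quantile_map(vals[sel], ref_vals,
                                     cfg.n_quantile_points)
    R[iu, ju] = out
    R[ju, iu] = out
    ids = coex.orf_ids
    return CoexpressionMatrix(pd.DataFrame(R, index=ids, columns=ids),
                              coex.n_shared.copy(),
                              min_shared=coex.min_shared, normalized=True)


def percentile_threshold(coex: CoexpressionMatrix,
                         top_fraction: float = 0.002) -> ThresholdResult:
    """Keep the top ``top_fraction`` of non-missing pairs (strict ">")."""
    v = coex.offdiag_values()
    if v.size == 0:
        raise ValueError("no non-missing pairs")
    thr = float(np.quantile(v, 1.0 - top_fraction))
    frac = float((v > thr).mean())
    return ThresholdResult(thr, "percentile", pair_fraction=frac)


def coverage_threshold(coex: CoexpressionMatrix, classes: pd.Series,
                       coverage: float = 0.90) -> ThresholdResult:
    """Pick the threshold that keeps >= ``coverage`` of canonical ORFs.

    Each canonical ORF's best partner score m_i = max non-missing rho to
    any other ORF; the threshold is the k-th largest m_i with
    k = ceil(coverage * n_canonical), and inclusion uses ">=" so the
    selected order statistic itself passes.
    """
    cls = classes.reindex(coex.orf_ids)
    canon = (cls == "canonical").to_numpy()
    if not canon.any():
        raise ValueError("no canonical ORFs")
    R = coex.rho.to_numpy().copy()
    np.fill_diagonal(R, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmax(R[canon], axis=1)
    m = m[~np.isnan(m)]
    if m.size == 0:
        raise ValueError("every canonical ORF has only missing rho")
    k = int(np.ceil(coverage * canon.sum()))
    k = min(max(k, 1), m.size)
    thr = float(np.sort(m)[::-1][k - 1])
    return ThresholdResult(thr, "coverage",
                           coverage=float((m >= thr).sum() / canon.sum()))
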