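"""Expression-level preprocessing: ORF filtering, detection masking, the
centered log-ratio transform on detected entries, TPM summaries, and the
sample-count convergence diagnostic for pairwise proportionality.

Counts below the detection floor are treated as missing rather than zero:
lowly expressed ORFs are unreliable at low counts, so undetected entries are
excluded both from the clr geometric mean and from all downstream pairwise
statistics (pairwise-complete analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix", "ClrMatrix", "ConvergenceResult",
    "filter_orfs", "detection_filter", "detection_mask", "clr_transform",
    "tpm", "median_tpm", "convergence_analysis",
]


@dataclass
class CountMatrix:
    """Raw ORF x sample counts with per-ORF class and length metadata."""

    counts: pd.DataFrame                 # ORFs x samples, integers >= 0
    orf_class: pd.Series                 # canonical | noncanonical
    orf_length_nt: pd.Series

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("ORF and sample ids must be unique")
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.orf_class = self.orf_class.reindex(c.index)
        self.orf_length_nt = self.orf_length_nt.reindex(c.index)
        if (self.orf_length_nt < 1).any():
            raise ValueError("ORF lengths must be >= 1")

    @classmethod
    def from_annotation(cls, counts: pd.DataFrame,
                        annotation: pd.DataFrame) -> "CountMatrix":
        ann = annotation.set_index("orf_id").reindex(counts.index)
        return cls(counts, ann["orf_class"],
                   (ann["end"] - ann["start"]).rename("orf_length_nt"))

    def subset(self, orf_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[orf_ids],
                           self.orf_class.loc[orf_ids],
                           self.orf_length_nt.loc[orf_ids])


@dataclass
class ClrMatrix:
    """clr-transformed values with NaN where undetected."""

    values: pd.DataFrame
    min_count: int = 5
    mean_clr: pd.Series = field(init=False)
    detected_samples: pd.Series = field(init=False)

    def __post_init__(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_clr = self.values.mean(axis=1)
        self.detected_samples = self.values.notna().sum(axis=1)


def filter_orfs(annotation: pd.DataFrame, min_len: int = 25,
                overlap_frac: float = 0.75,
                sequences: dict | None = None) -> pd.DataFrame:
    """ORF-list filtering before quantification.

    Removes, in order: ORFs shorter than the aligner k-mer size
    (``min_len`` nt); for same-strand overlapping pairs where the overlap
    exceeds ``overlap_frac`` of either ORF, the shorter ORF; exact
    duplicate sequences when ``sequences`` (orf_id -> str) is supplied,
    keeping the lexicographically first id.
    """
    ann = annotation.copy()
    if (ann["start"] >= ann["end"]).any():
        raise ValueError("malformed intervals: start must be < end")
    length = ann["end"] - ann["start"]
    ann = ann[length >= min_len]

    drop: set = set()
    for (_, _), grp in ann.groupby(["chrom", "strand"], sort=False):
        g = grp.sort_values("start")
        ids = g["orf_id"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                if starts[j] >= ends[i]:
                    break
                ov = min(ends[i], ends[j]) - starts[j]
                len_i, len_j = ends[i] - starts[i], ends[j] - starts[j]
                if ov > overlap_frac * min(len_i, len_j) or \
                        ov > overlap_frac * max(len_i, len_j):
                    shorter = ids[i] if len_i < len_j else ids[j]
                    if len_i == len_j:   # tie: drop the later id
                        shorter = max(ids[i], ids[j])
                    drop.add(shorter)
    ann = ann[~ann["orf_id"].isin(drop)]

    if sequences is not None:
        seen: dict[str, str] = {}
        dup: set = set()
        for oid in sorted(ann["orf_id"]):
            seq = sequences.get(oid)
            if seq is None:
                continue
            if seq in seen:
                dup.add(oid)
            else:
                seen[seq] = oid
        ann = ann[~ann["orf_id"].isin(dup)]
    return ann.reset_index(drop=True)


def detection_mask(counts: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """Boolean detection mask: True where count >= ``min_count``."""
    return counts >= min_count


def detection_filter(cm: CountMatrix, min_count: int = 5,
                     min_samples: int = 400) -> CountMatrix:
    """Keep ORFs detected (count >= min_count) in >= min_samples samples."""
    keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    return cm.subset(cm.counts.index[keep])


def clr_transform(cm: CountMatrix, min_count: int = 5) -> ClrMatrix:
    """Centered log-ratio transform over detected entries, per sample.

    For sample j with detected counts x: clr(x)_i = ln x_i - mean_k ln x_k,
    the mean running over the detected ORFs of that sample only. Undetected
    entries come out NaN.
    """
    x = cm.counts.to_numpy(dtype=float)
    mask = x >= min_count
    logx = np.where(mask, np.log(np.where(mask, x, 1.0)), np.nan)
    n_det = mask.sum(axis=0)
    if (n_det == 0).any():
        warnings.warn("sample(s) with zero detected ORFs are all-missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        colmean = np.nansum(logx, axis=0) / np.where(n_det > 0, n_det, np.nan)
    vals = logx - colmean[None, :]
    return ClrMatrix(pd.DataFrame(vals, index=cm.counts.index,
                                  columns=cm.counts.columns),
                     min_count=min_count)


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million per sample: 1e6 * (c_i/L_i) / sum_j (c_j/L_j)."""
    rate = cm.counts.to_numpy(dtype=float) / \
        cm.orf_length_nt.to_numpy(dtype=float)[:, None]
    tot = rate.sum(axis=0)
    if (tot == 0).any():
        warnings.warn("all-zero sample(s): TPM reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 1e6 * rate / np.where(tot > 0, tot, np.nan)
    vals = np.nan_to_num(vals)
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def median_tpm(cm: CountMatrix) -> pd.Series:
    """Per-ORF median TPM across all samples."""
    return tpm(cm).median(axis=1).rename("median_tpm")


@dataclass
class ConvergenceResult:
    converged: bool
    convergence_index: int | None       # sample count, multiple of bin_size
    fluctuations: np.ndarray            # max(rho) - min(rho) per bin
    bin_size: int
    threshold: float


def convergence_analysis(a_x, a_y, bin_size: int = 10,
                         threshold: float = 0.05,
                         seed: int = 0) -> ConvergenceResult:
    """How many samples does the proportionality of a pair need to settle?

    Samples where both ORFs are detected are shuffled (seeded), rho is
    recomputed after each added sample, and the resulting trajectory is
    split into consecutive bins of ``bin_size`` samples. The fluctuation of
    a bin is max(rho) - min(rho) within it; the pair converges at the first
    bin whose fluctuation is <= ``threshold``.
    """
    a_x = np.asarray(a_x, dtype=float)
    a_y = np.asarray(a_y, dtype=float)
    shared = ~(np.isnan(a_x) | np.isnan(a_y))
    x, y = a_x[shared], a_y[shared]
    n = x.size
    if n < 2 * bin_size:
        raise ValueError("need at least 2*bin_size shared samples")
    order = np.random.default_rng(seed).permutation(n)
    x, y = x[order], y[order]

    k = np.arange(1, n + 1, dtype=float)
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, syy = np.cumsum(x * x), np.cumsum(y * y)
    sxy = np.cumsum(x * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        varx = (sxx - sx ** 2 / k)
        vary = (syy - sy ** 2 / k)
        cov = (sxy - sx * sy / k)
        rho = 2.0 * cov / (varx + vary)
    rho = rho[1:]                        # defined from the 2nd sample on

    n_bins = n // bin_size
    flucts = np.empty(n_bins)
    for b in range(n_bins):
        lo = max(2, b * bin_size + 1)    # sample indices in (b*bs, (b+1)*bs]
        hi = (b + 1) * bin_size
        seg = rho[lo - 2: hi - 1]
        flucts[b] = np.nanmax(seg) - np.nanmin(seg)
    hit = np.where(flucts <= threshold)[0]
    if hit.size:
        return ConvergenceResult(True, int((hit[0] + 1) * bin_size),
                                 flucts, bin_size, threshold)
    return ConvergenceResult(False, None, flucts, bin_size, threshold)
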