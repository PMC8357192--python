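"""GAG-depletion segmentation, ROC threshold selection, group statistics.

The GAG-depleted superficial layer has a reduced channel-1 intensity
ratio, so it is segmented per image column as the surface-contiguous run
of tissue pixels whose channel-1 ratio falls below a threshold (default
0.25, re-derivable from ground truth by ROC analysis).  The per-column
run length times the pixel pitch is the depletion thickness; its mean
over tissue columns summarizes the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import SurfaceMap
from .maps import FLImMaps

__all__ = [
    "DEFAULT_THRESHOLD",
    "ROCResult",
    "SegmentationResult",
    "GroupComparison",
    "roc_threshold",
    "segment_depletion",
    "roi_summary",
    "compare_groups",
]

DEFAULT_THRESHOLD = 0.25


@dataclass
class ROCResult:
    """ROC sweep of "depleted if value < threshold" over all midpoints
    between sorted unique values (plus open endpoints)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_threshold: float


def roc_threshold(values: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC analysis of channel-1 intensity ratio against depletion truth.

    Positives (depleted) are predicted by ``value < threshold``.  The AUC
    is the trapezoid over (fpr, tpr); the chosen threshold maximizes
    Youden's J = TPR − FPR, with ties resolved toward the midpoint of the
    two class means.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    if labels.all() or not labels.any():
        raise ValueError("ROC analysis requires both classes to be present")
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo = uniq[0] - 1.0
    hi = uniq[-1] + 1.0
    thresholds = np.concatenate([[lo], mids, [hi]])
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    tpr = np.searchsorted(pos, thresholds, side="left") / pos.size
    fpr = np.searchsorted(neg, thresholds, side="left") / neg.size
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    midpoint = (pos.mean() + neg.mean()) / 2.0
    chosen = float(thresholds[best[np.argmin(np.abs(thresholds[best] - midpoint))]])
    return ROCResult(thresholds, tpr, fpr, auc, chosen)


@dataclass
class SegmentationResult:
    depleted_mask: np.ndarray
    thickness_per_column: np.ndarray  # mm; NaN for columns without tissue
    mean_thickness: float
    threshold_used: float


def segment_depletion(
    maps: FLImMaps,
    surface: SurfaceMap,
    threshold: float = DEFAULT_THRESHOLD,
) -> SegmentationResult:
    """Label the surface-contiguous sub-threshold layer in each column.

    Starting from the first valid pixel at or below the detected surface,
    pixels are labelled depleted while their channel-1 intensity ratio
    stays below ``threshold``; the run stops at the first pixel at or
    above it (isolated deep sub-threshold pixels are not counted).
    """
    n_rows, n_cols = maps.valid.shape
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    thickness = np.full(n_cols, np.nan)
    for c in range(n_cols):
        rows = np.flatnonzero(maps.valid[:, c])
        if rows.size == 0:
            continue
        s = surface.surface_row[c]
        if np.isfinite(s):
            rows = rows[rows >= s - 0.5]
            if rows.size == 0:
                thickness[c] = 0.0
                continue
        count = 0
        r = rows[0]
        while r < n_rows and maps.valid[r, c] and maps.ratio[r, c, 0] < threshold:
            mask[r, c] = True
            count += 1
            r += 1
        thickness[c] = count * maps.pixel_pitch
    if np.all(np.isnan(thickness)):
        raise ValueError("no tissue columns to segment")
    return SegmentationResult(
        mask, thickness, float(np.nanmean(thickness)), float(threshold)
    )


def roi_summary(maps: FLImMaps, roi_mask: np.ndarray) -> dict:
    """Arithmetic means of lifetime and intensity ratio over the valid
    pixels of a region of interest."""
    roi = np.asarray(roi_mask, dtype=bool) & maps.valid
    n = int(roi.sum())
    if n == 0:
        raise ValueError("ROI does not intersect any valid pixels")
    return {
        "n": n,
        "mean_lt": maps.lt[roi].mean(axis=0),
        "mean_ratio": maps.ratio[roi].mean(axis=0),
    }


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons."""

    group_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    mean_differences: np.ndarray  # [i, j] = mean_i - mean_j
    f_statistic: float
    p_value: float
    tukey_p: np.ndarray  # pairwise adjusted p-values
    degenerate: bool = False


def compare_groups(samples: dict[str, np.ndarray]) -> GroupComparison:
    """Compare per-sample summaries (e.g. ROI mean depletion thickness)
    across treatment groups.

    Delegates to scipy's one-way ANOVA and Tukey honest-significant-
    difference test (studentized-range adjustment at family level 0.05).
    """
    names = list(samples)
    groups = [np.asarray(samples[g], dtype=float).ravel() for g in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 samples each")
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    diffs = means[:, None] - means[None, :]
    if np.all(sds == 0) and np.all(diffs == 0):
        k = len(groups)
        return GroupComparison(
            names, means, sds, diffs, float("nan"), float("nan"),
            np.full((k, k), np.nan), degenerate=True,
        )
    f, p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    return GroupComparison(
        names, means, sds, diffs, float(f), float(p), np.asarray(tukey.pvalue)
    )
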