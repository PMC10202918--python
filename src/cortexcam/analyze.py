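"""Aggregate saliency heatmaps and compute the study's summary statistics.

Heatmaps from individual evaluated trials are averaged within cells
defined by (group, correctness of the prediction); the patient-correct
cell is the primary object of interest, mirrored against the incorrect
cell as a specificity contrast.  ROI time courses reduce a 3d aggregate to
per-time-bin means over a region's projected pixel footprint, and a
rank-based AUC quantifies how well |relevance| detects the voxels of the
planted effect.  Group statistics (pooled-variance t test, Fisher's exact
test, Cohen's d from summary statistics) and one-tailed Pearson
correlations match the corresponding reference implementations in scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import SourceTrialSet, SurfaceGeometry
from .volumize import BINS_3D_MS

__all__ = [
    "AggregateHeatmap",
    "RoiTimeCourse",
    "aggregate_heatmaps",
    "roi_time_course",
    "localization_score",
    "cohen_d",
    "independent_t_test",
    "fisher_exact",
    "pearson_one_tailed",
    "roi_mean_current_density",
    "group_stats_table",
]


@dataclass
class AggregateHeatmap:
    """Mean heatmap over the samples matching one (group, correctness)
    cell, with the sample count; ``values`` is None for an empty cell
    (reported as missing, never as zeros)."""

    values: np.ndarray | None
    n_samples: int
    method: str
    group: str  # "patient" | "control" | "all"
    correctness: str  # "correct" | "incorrect" | "all"


def aggregate_heatmaps(
    heatmaps: np.ndarray,
    predictions: np.ndarray,
    labels: np.ndarray,
    group_filter: str = "patient",
    correctness: str = "correct",
    method: str = "",
) -> AggregateHeatmap:
    """Elementwise mean of the heatmaps in one (group, correctness) cell.

    ``heatmaps`` is (n_samples, ...) aligned with binary ``predictions``
    and ``labels`` (1 = patient).  ``group_filter`` and ``correctness``
    accept "all" to disable that predicate.
    """
    heatmaps = np.asarray(heatmaps)
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if not (len(heatmaps) == len(predictions) == len(labels)):
        raise ValueError("heatmaps, predictions and labels must align")
    sel = np.ones(len(heatmaps), dtype=bool)
    if group_filter != "all":
        sel &= labels == (1 if group_filter == "patient" else 0)
    if correctness != "all":
        sel &= (predictions == labels) == (correctness == "correct")
    n = int(sel.sum())
    values = heatmaps[sel].mean(axis=0) if n else None
    return AggregateHeatmap(
        values=values, n_samples=n, method=method,
        group=group_filter, correctness=correctness,
    )


@dataclass
class RoiTimeCourse:
    """Per-time-bin mean relevance over an ROI footprint, with the peak."""

    windows_ms: tuple[tuple[float, float], ...]
    values: np.ndarray
    peak_window_ms: tuple[float, float]


def roi_time_course(
    agg: AggregateHeatmap,
    roi_pixels: np.ndarray,
    windows_ms: tuple[tuple[float, float], ...] = BINS_3D_MS,
    magnitude: bool = True,
) -> RoiTimeCourse:
    """Reduce a 3d aggregate heatmap to an ROI time course.

    ``roi_pixels`` is a (H, W) boolean mask.  By default the per-bin value
    is the mean |relevance| over the footprint: the sign of a relevance
    contribution tracks the direction of the group difference (an
    attenuated response contributes negatively to the patient score), so
    magnitude is the right notion of importance.  The peak window is the
    argmax bin; ties break to the earliest bin (numpy argmax order).
    """
    if agg.values is None:
        raise ValueError("cannot take a time course of an empty aggregate cell")
    if agg.values.ndim != 3:
        raise ValueError("roi_time_course needs a 3d heatmap (H, W, bins)")
    roi_pixels = np.asarray(roi_pixels, dtype=bool)
    if not roi_pixels.any():
        raise ValueError("ROI mask is empty")
    if roi_pixels.shape != agg.values.shape[:2]:
        raise ValueError("ROI mask shape does not match the heatmap grid")
    data = np.abs(agg.values) if magnitude else agg.values
    vals = data[roi_pixels].mean(axis=0)
    if len(vals) != len(windows_ms):
        raise ValueError("window list does not match the heatmap's bin count")
    peak = int(np.argmax(vals))
    return RoiTimeCourse(
        windows_ms=tuple(windows_ms),
        values=vals,
        peak_window_ms=tuple(windows_ms[peak]),
    )


def localization_score(agg: AggregateHeatmap, planted_mask: np.ndarray) -> float:
    """Rank AUC of |relevance| as a detector of planted-effect voxels.

    1.0 means every planted voxel outranks every other voxel, 0.5 is
    chance.  The mask must be non-degenerate (neither empty nor full).
    """
    if agg.values is None:
        raise ValueError("empty aggregate cell has no localization score")
    mask = np.asarray(planted_mask, dtype=bool)
    if mask.shape != agg.values.shape:
        raise ValueError("mask shape must match the heatmap shape")
    n_pos = int(mask.sum())
    if n_pos == 0 or n_pos == mask.size:
        raise ValueError("planted mask must be neither empty nor full")
    scores = np.abs(agg.values).ravel()
    flat = mask.ravel()
    ranks = stats.rankdata(scores)
    n_neg = mask.size - n_pos
    return float((ranks[flat].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# summary statistics


def cohen_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Standardized mean difference (group2 - group1) / pooled SD.

    Pooled SD uses (n-1) weights.  Sign convention: group 1 is the
    control group, group 2 the patient group.  Returns NaN when the
    pooled SD is zero (undefined).
    """
    if sd1 < 0 or sd2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need sds >= 0 and group sizes >= 2")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        return float("nan")
    return float((mean2 - mean1) / s_pooled)


def independent_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t test from summary statistics.

    Returns (t, two-sided p) with n1 + n2 - 2 degrees of freedom.  Equal
    means with zero variance in both groups give (0, 1) by convention.
    """
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (point-probability
    rule, as in scipy)."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pearson_one_tailed(
    x: np.ndarray, y: np.ndarray, direction: str = "positive"
) -> tuple[float, float]:
    """Pearson correlation with a one-tailed p in the stated direction.

    p is computed from t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees
    of freedom.  Zero variance in either variable -> (NaN, NaN).
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    alt = "greater" if direction == "positive" else "less"
    res = stats.pearsonr(x, y, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def roi_mean_current_density(
    trial_sets: list[SourceTrialSet],
    surface: SurfaceGeometry,
    roi_region: int,
    window_ms: tuple[float, float],
) -> pd.DataFrame:
    """Per-subject mean current density over trials, ROI vertices and a
    time window — the quantity correlated against clinical scores."""
    mask = surface.region_mask(roi_region)
    rows = []
    for ts in trial_sets:
        times = ts.times_ms
        lo, hi = window_ms
        sel = (times >= lo) & (times < hi)
        if not sel.any():
            raise ValueError(f"epoch does not cover window [{lo}, {hi}) ms")
        value = float(ts.data[:, mask][:, :, sel].mean())
        rows.append(
            {"subject_id": ts.subject_id, "group": ts.group, "roi_mean": value}
        )
    return pd.DataFrame(rows)


def group_stats_table(
    per_subject: pd.DataFrame,
    value_cols: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-variable control vs patient summaries with t, p and Cohen's d,
    mirroring a clinical demographics table layout."""
    ctl = per_subject[per_subject[group_col] == "control"]
    pat = per_subject[per_subject[group_col] == "patient"]
    rows = []
    for col in value_cols:
        c, p = ctl[col].to_numpy(float), pat[col].to_numpy(float)
        t, pv = independent_t_test(
            c.mean(), c.std(ddof=1), len(c), p.mean(), p.std(ddof=1), len(p)
        )
        d = cohen_d(c.mean(), c.std(ddof=1), len(c), p.mean(), p.std(ddof=1), len(p))
        rows.append(
            {
                "variable": col,
                "control_mean": c.mean(), "control_sd": c.std(ddof=1),
                "patient_mean": p.mean(), "patient_sd": p.std(ddof=1),
                "t": t, "p_value": pv, "cohen_d": d,
            }
        )
    return pd.DataFrame(rows)
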