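"""Segmentation and landmark-error metrics.

Pixel metrics from the confusion counts of a predicted vs. reference mask:
accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP), recall
(sensitivity) = TP/(TP+FN), F1 = 2*precision*recall/(precision+recall),
IoU = TP/(TP+FP+FN).  Landmark accuracy uses MAPE = (100/n) * sum(|actual -
predicted| / |actual|) and RMSE = sqrt(sum((actual - predicted)^2) / n).

Report aggregation is per-landmark first: the overall RMSE/MAPE of a report
are unweighted arithmetic means of the seven per-landmark values (pooling
over all pairs would weight landmarks by sample count and does not reproduce
the standard per-landmark summary table).  Zero-denominator metrics are NaN
("undefined"), never silently 0 — degenerate masks must stay visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .geometry import BROW_LANDMARKS, LANDMARK_NAMES, LandmarkSet, as_mask_array

UNDEFINED = float("nan")


# ---------------------------------------------------------------------------
# Pixel-level segmentation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegMetrics:
    """The five pixel metrics; undefined ratios are NaN."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN between two binary masks of identical frame."""
    p = as_mask_array(predicted)
    t = as_mask_array(truth)
    if p.shape != t.shape:
        raise InputError(f"mask frames differ: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def seg_metrics(counts: ConfusionCounts) -> SegMetrics:
    """Apply the five metric formulas; zero denominators yield NaN."""
    if counts.total <= 0:
        raise InputError("confusion counts are all zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = UNDEFINED
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return SegMetrics(
        accuracy=_ratio(tp + tn, counts.total),
        precision=precision,
        recall=recall,
        f1=f1,
        iou=_ratio(tp, tp + fp + fn),
    )


# ---------------------------------------------------------------------------
# Landmark error metrics
# ---------------------------------------------------------------------------

def _paired(actual, predicted):
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise InputError(f"length mismatch: {a.size} vs {p.size}")
    if a.size == 0:
        raise InputError("need at least one value pair")
    return a, p


def mape(actual, predicted) -> float:
    """Mean absolute percentage error: (100/n) * sum(|a - p| / |a|)."""
    a, p = _paired(actual, predicted)
    zero = np.flatnonzero(a == 0)
    if zero.size:
        raise InputError(
            f"MAPE undefined: actual value at index {zero[0]} is zero")
    return float(100.0 / a.size * np.sum(np.abs(a - p) / np.abs(a)))


def rmse(actual, predicted) -> float:
    """Root mean square error: sqrt(sum((a - p)^2) / n)."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


# ---------------------------------------------------------------------------
# Report aggregation (per-landmark table with overall means)
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Per-landmark RMSE (mm) / MAPE (%) plus unweighted overall means."""

    per_landmark: pd.DataFrame            # index: landmark; rmse_mm, mape_pct, n
    overall_rmse_mm: float
    overall_mape_pct: float
    brow_subgroup_mape_pct: float
    brow_subgroup_rmse_mm: float
    excluded: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the per-landmark summary with overall rows."""
        df = self.per_landmark.copy()
        df.loc["Overall"] = {"rmse_mm": self.overall_rmse_mm,
                             "mape_pct": self.overall_mape_pct,
                             "n": df["n"].sum()}
        return df


def aggregate_landmark_table(per_landmark_rmse: dict[str, float],
                             per_landmark_mape: dict[str, float]):
    """Summary-table aggregation from per-landmark values.

    Returns (overall_rmse, overall_mape, brow_subgroup_mape): unweighted
    means over the seven landmarks, and the mean MAPE over the five brow
    landmarks (MBE, ML, PC, LL, LBE).
    """
    missing = [k for k in LANDMARK_NAMES if k not in per_landmark_rmse
               or k not in per_landmark_mape]
    if missing:
        raise InputError(f"missing landmarks in table: {missing}")
    overall_rmse = float(np.mean([per_landmark_rmse[k] for k in LANDMARK_NAMES]))
    overall_mape = float(np.mean([per_landmark_mape[k] for k in LANDMARK_NAMES]))
    brow_mape = float(np.mean([per_landmark_mape[k] for k in BROW_LANDMARKS]))
    return overall_rmse, overall_mape, brow_mape


def landmark_error_report(predicted: list[LandmarkSet],
                          truth: list[LandmarkSet],
                          exclude_occluded: bool = False) -> ErrorReport:
    """Aggregate paired landmark sets into a per-landmark error table.

    Pairs where either value is missing (NaN) are excluded per landmark,
    with exclusion counts reported; ``exclude_occluded=True`` additionally
    drops pairs whose occlusion flag is set in either member.  Overall
    values are unweighted means across the seven landmarks.
    """
    if len(predicted) != len(truth):
        raise InputError("predicted and truth lists differ in length")
    if not predicted:
        raise InputError("need at least one landmark-set pair")

    rows = []
    excluded: dict[str, int] = {}
    rmse_by: dict[str, float] = {}
    mape_by: dict[str, float] = {}
    for name in LANDMARK_NAMES:
        a, p, dropped = [], [], 0
        for pred_set, true_set in zip(predicted, truth):
            pv = pred_set.values()[name]
            tv = true_set.values()[name]
            bad = math.isnan(pv) or math.isnan(tv)
            if exclude_occluded:
                bad = bad or pred_set.occlusion_flags.get(name, False) \
                    or true_set.occlusion_flags.get(name, False)
            if bad:
                dropped += 1
            else:
                a.append(tv)
                p.append(pv)
        excluded[name] = dropped
        if not a:
            raise InputError(
                f"no usable pairs for landmark {name} after exclusions")
        rmse_by[name] = rmse(a, p)
        # MAPE denominators are the reference values; zero references for
        # MRD can occur (lid at pupil center) and are skipped for MAPE only
        an, pn = np.asarray(a), np.asarray(p)
        nz = an != 0
        mape_by[name] = mape(an[nz], pn[nz]) if nz.any() else UNDEFINED
        rows.append({"landmark": name, "rmse_mm": rmse_by[name],
                     "mape_pct": mape_by[name], "n": len(a)})

    table = pd.DataFrame(rows).set_index("landmark")
    overall_rmse, overall_mape, brow_mape = aggregate_landmark_table(
        rmse_by, mape_by)
    brow_rmse = float(np.mean([rmse_by[k] for k in BROW_LANDMARKS]))
    return ErrorReport(
        per_landmark=table,
        overall_rmse_mm=overall_rmse,
        overall_mape_pct=overall_mape,
        brow_subgroup_mape_pct=brow_mape,
        brow_subgroup_rmse_mm=brow_rmse,
        excluded=excluded,
    )
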