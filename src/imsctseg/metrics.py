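"""Segmentation evaluation metrics and their aggregation.

Per structure and subject: Dice (with the convention that a false
positive prediction for a structure absent in the subject scores 0),
detection flags at a 6 mm^3 physical-overlap threshold, voxel precision
and recall, and signed / absolute relative volume differences (negative
signed difference = over-segmentation).  Cohort numbers are computed per
split and then aggregated as mean +/- population standard deviation
across repeated random splits.

Undefined cases are excluded from averages rather than zero-filled:
empty-ground-truth + empty-prediction Dice, precision of an empty
prediction, and volume differences with empty ground truth.  Exclusion
counts are reported alongside the aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: evaluation order of the label channels
STRUCTURES = ("whole", "tumor", "cavity", "edema")


@dataclass
class MetricsConfig:
    detection_overlap_mm3: float = 6.0
    structures: tuple[str, ...] = STRUCTURES

    def __post_init__(self) -> None:
        if self.detection_overlap_mm3 <= 0:
            raise ValueError("detection overlap threshold must be positive")


def _check_aligned(pred, gt):
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def dice_score(pred_bin, gt_bin):
    """Dice overlap ``2|P n G| / (|P| + |G|)``.

    Empty ground truth with a non-empty prediction scores 0 (false
    positive); empty-empty returns ``None`` (absent case, excluded from
    cohort averages).
    """
    pred, gt = _check_aligned(pred_bin, gt_bin)
    p, g = int(pred.sum()), int(gt.sum())
    if g == 0:
        return None if p == 0 else 0.0
    inter = int((pred & gt).sum())
    return 2.0 * inter / (p + g)


def detection_flags(pred_bin, gt_bin, spacing, cfg: MetricsConfig | None = None):
    """``(true_positive, false_positive)`` detection flags.

    With ground truth present, the structure counts as detected when the
    physical overlap reaches the threshold (inclusive).  With ground
    truth absent, a prediction of at least the same physical volume
    counts as a false positive; flags that do not apply are ``None``.
    """
    cfg = cfg or MetricsConfig()
    pred, gt = _check_aligned(pred_bin, gt_bin)
    voxel_mm3 = float(np.prod(spacing))
    if gt.any():
        overlap = int((pred & gt).sum()) * voxel_mm3
        return bool(overlap >= cfg.detection_overlap_mm3), None
    if not pred.any():
        return None, False
    return None, bool(int(pred.sum()) * voxel_mm3 >= cfg.detection_overlap_mm3)


def precision_recall(pred_bin, gt_bin):
    """Voxelwise ``(precision, recall)``; ``None`` where undefined."""
    pred, gt = _check_aligned(pred_bin, gt_bin)
    p, g = int(pred.sum()), int(gt.sum())
    inter = int((pred & gt).sum())
    precision = inter / p if p > 0 else None
    recall = inter / g if g > 0 else None
    return precision, recall


def volume_differences(pred_bin, gt_bin, spacing):
    """``(rvd, avd)`` relative and absolute volume difference.

    ``rvd = (V_gt - V_pred) / V_gt`` so over-segmentation is negative;
    undefined (``None, None``) for empty ground truth.
    """
    pred, gt = _check_aligned(pred_bin, gt_bin)
    voxel_mm3 = float(np.prod(spacing))
    v_gt = int(gt.sum()) * voxel_mm3
    if v_gt == 0:
        return None, None
    v_pred = int(pred.sum()) * voxel_mm3
    rvd = (v_gt - v_pred) / v_gt
    return rvd, abs(rvd)


def bbox_inclusion(gt_mask, bbox):
    """Whether every foreground voxel lies inside the half-open box.

    Returns ``(fully_contained, contained_fraction)``; an empty mask is
    contained by convention.
    """
    gt = np.asarray(gt_mask) > 0
    idx = np.argwhere(gt)
    if idx.size == 0:
        return True, 1.0
    lo = np.asarray(bbox.lo)
    hi = np.asarray(bbox.hi)
    inside = np.all((idx >= lo) & (idx < hi), axis=1)
    frac = float(inside.mean())
    return bool(inside.all()), frac


# ---------------------------------------------------------------------------
# Per-subject evaluation and aggregation


def evaluate_subject(
    pred4, gt4, spacing, subject_id: str = "", cfg: MetricsConfig | None = None
) -> pd.DataFrame:
    """All metrics for one subject; 4-channel binary inputs in the package
    channel order (tumor, cavity, edema, whole)."""
    from .imgio import LABEL_CHANNELS

    cfg = cfg or MetricsConfig()
    rows = []
    for structure in cfg.structures:
        i = LABEL_CHANNELS.index(structure)
        pred, gt = pred4[i], gt4[i]
        tp, fp = detection_flags(pred, gt, spacing, cfg)
        prec, rec = precision_recall(pred, gt)
        rvd, avd = volume_differences(pred, gt, spacing)
        rows.append(
            {
                "subject_id": subject_id,
                "structure": structure,
                "gt_present": bool(np.asarray(gt).any()),
                "dice": dice_score(pred, gt),
                "true_positive": tp,
                "false_positive": fp,
                "precision": prec,
                "recall": rec,
                "rvd": rvd,
                "avd": avd,
            }
        )
    return pd.DataFrame(rows)


_MEAN_METRICS = ("dice", "precision", "recall", "rvd", "avd")


def _cohort_means(report: pd.DataFrame) -> pd.DataFrame:
    """Per-structure cohort means for one split, excluding undefined
    entries; detection rates over the subjects where they apply."""
    out = []
    for structure, grp in report.groupby("structure", sort=False):
        row = {"structure": structure}
        for metric in _MEAN_METRICS:
            vals = grp[metric].dropna()
            row[metric] = float(vals.mean()) if len(vals) else None
            row[f"n_{metric}"] = int(len(vals))
        tp = grp["true_positive"].dropna()
        fp = grp["false_positive"].dropna()
        row["tp_rate"] = float(tp.mean()) if len(tp) else None
        row["fp_rate"] = float(fp.mean()) if len(fp) else None
        row["n_tp"] = int(len(tp))
        row["n_fp"] = int(len(fp))
        out.append(row)
    return pd.DataFrame(out)


@dataclass
class MetricsReport:
    """Mean +/- std of cohort metrics across repeated random splits."""

    summary: pd.DataFrame
    per_split: list[pd.DataFrame] = field(default_factory=list)


def aggregate(split_reports: list[pd.DataFrame]) -> MetricsReport:
    """Aggregate per-subject reports from one or more splits.

    Each input frame holds the per-subject rows of one split (as produced
    by :func:`evaluate_subject`, concatenated).  The summary carries, per
    structure and metric, the mean and the population standard deviation
    of the per-split cohort means; structures with no evaluable subject
    in any split are marked not evaluable (``NaN`` with ``n=0``).
    """
    if not split_reports:
        raise ValueError("need at least one split report")
    per_split = [_cohort_means(rep) for rep in split_reports]
    rows = []
    structures = per_split[0]["structure"].tolist()
    rate_metrics = _MEAN_METRICS + ("tp_rate", "fp_rate")
    for structure in structures:
        row = {"structure": structure}
        for metric in rate_metrics:
            vals = [
                float(sp.loc[sp["structure"] == structure, metric].iloc[0])
                for sp in per_split
                if pd.notna(sp.loc[sp["structure"] == structure, metric].iloc[0])
            ]
            row[f"{metric}_mean"] = float(np.mean(vals)) if vals else float("nan")
            row[f"{metric}_std"] = float(np.std(vals)) if vals else float("nan")
            row[f"{metric}_n_splits"] = len(vals)
        rows.append(row)
    return MetricsReport(summary=pd.DataFrame(rows), per_split=per_split)
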