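"""Desk-scale end-to-end study on synthetic phantom cohorts.

Trains the full two-stage cascade (cord localizer, then multiclass tumor
segmenter) on a reduced problem — 40 phantoms on a 96 x 48 x 24
standard grid, depth-3 networks with 4 / 8 base filters, 32 x 32 x 16
patches with a 16 x 16 x 16 stride — and evaluates the held-out test
subjects in standard space.  This is the package's parameter-recovery
experiment: it checks that the pipeline as a whole can learn the phantom
generative model, and it is what the acceptance script reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, mask_to_bbox, run_cascade
from .errors import LocalizationFailure
from .imgio import (
    ImageVolume,
    PreprocConfig,
    preprocess_to_standard,
    zscore_normalize,
)
from .metrics import MetricsConfig, bbox_inclusion, dice_score, evaluate_subject
from .net3d import UNetConfig
from .phantom import PhantomSpec, SubjectRecord, generate_cohort
from .train import Sample, TrainConfig, TrainedModel, split_dataset, train_model


@dataclass
class ToyStudyConfig:
    """Problem sizes of the desk-scale study.

    Epoch budgets are set to where the stages converge on phantoms (the
    cosine schedule spans the budget); both are well under the clinical
    schedule of 200 epochs.
    """

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (96, 48, 24)
    localizer: UNetConfig = field(
        default_factory=lambda: UNetConfig(
            in_channels=1, out_channels=1, depth=3, base_filters=4, dropout_rate=0.1
        )
    )
    segmenter: UNetConfig = field(
        default_factory=lambda: UNetConfig(
            in_channels=2, out_channels=4, depth=3, base_filters=8, dropout_rate=0.1
        )
    )
    seg_patch: tuple[int, int, int] = (32, 32, 16)
    seg_stride: tuple[int, int, int] = (16, 16, 16)
    loc_epochs: int = 8
    seg_epochs: int = 6
    patience: int = 4
    bbox_margin_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)


@dataclass
class PreparedSubject:
    record: SubjectRecord
    t1_std: np.ndarray  # z-scored standard grid
    t2_std: np.ndarray
    labels_std: np.ndarray  # (4, grid) uint8
    tube_std: np.ndarray  # (grid,) uint8


@dataclass
class ToyStudyResult:
    results: dict
    per_subject: pd.DataFrame
    localizer: TrainedModel
    segmenter: TrainedModel
    split: object
    config: ToyStudyConfig


def prepare_subject(record: SubjectRecord, preproc: PreprocConfig) -> PreparedSubject:
    """Resample / crop / normalize one subject into standard space."""
    t2, _ = preprocess_to_standard(record.t2w, preproc, interp="linear")
    t1, _ = preprocess_to_standard(record.gd_t1w, preproc, interp="linear")
    labels = np.stack(
        [
            preprocess_to_standard(
                ImageVolume(ch, record.labels.spacing),
                preproc,
                interp="nearest",
                normalize=False,
            )[0].data.astype(np.uint8)
            for ch in record.labels.data
        ]
    )
    tube, _ = preprocess_to_standard(
        record.cord_mask, preproc, interp="nearest", normalize=False
    )
    return PreparedSubject(
        record=record,
        t1_std=t1.data.astype(np.float32),
        t2_std=t2.data.astype(np.float32),
        labels_std=labels,
        tube_std=tube.data.astype(np.uint8),
    )


def _segmenter_sample(prep: PreparedSubject, preproc: PreprocConfig, margin_mm) -> Sample:
    """Training crop around the ground-truth cord tube (the cascade's
    training-time stand-in for the manual cord mask)."""
    bbox = mask_to_bbox(prep.tube_std, margin_mm, preproc.target_spacing)
    sl = bbox.slices()
    spacing = preproc.target_spacing
    crop_t1 = zscore_normalize(ImageVolume(prep.t1_std[sl], spacing)).data
    crop_t2 = zscore_normalize(ImageVolume(prep.t2_std[sl], spacing)).data
    return Sample(
        subject_id=prep.record.subject_id,
        image=np.stack([crop_t1, crop_t2]).astype(np.float32),
        target=prep.labels_std[(slice(None),) + sl],
    )


def _cohort_dice(frame: pd.DataFrame, structure: str, restricted: bool):
    sub = frame[frame["structure"] == structure]
    if restricted:
        sub = sub[sub["gt_present"]]
    vals = sub["dice"].dropna()
    return float(vals.mean()) if len(vals) else None


def run_toy_study(
    seed: int, cfg: ToyStudyConfig | None = None, verbose: bool = False
) -> ToyStudyResult:
    """Generate, train, segment and evaluate one phantom study.

    All randomness (cohort, split, weight init, dropout, augmentation)
    derives from ``seed``.
    """
    cfg = cfg or ToyStudyConfig()
    preproc = PreprocConfig(target_spacing=(1.0, 1.0, 2.0), crop_shape=cfg.grid_shape)
    spec = PhantomSpec(grid_shape=cfg.grid_shape)
    records, manifest = generate_cohort(cfg.n_subjects, spec, seed=seed)
    prepared = {r.subject_id: prepare_subject(r, preproc) for r in records}
    split = split_dataset(manifest, (0.6, 0.2, 0.2), seed=seed + 101)

    if verbose:
        print(f"cohort: {cfg.n_subjects} subjects; split "
              f"{len(split.train)}/{len(split.validation)}/{len(split.test)}")

    # stage 1: cord localizer on T2w, full-grid single patch, batch 1
    loc_cfg = TrainConfig(
        lr=0.001,
        max_epochs=cfg.loc_epochs,
        patience=min(cfg.patience, cfg.loc_epochs),
        batch_size=1,
        patch_size=cfg.grid_shape,
        stride=cfg.grid_shape,
        seed=seed + 202,
    )
    loc_train = [
        Sample(s, prepared[s].t2_std[None], prepared[s].tube_std[None])
        for s in split.train
    ]
    loc_val = [
        Sample(s, prepared[s].t2_std[None], prepared[s].tube_std[None])
        for s in split.validation
    ]
    localizer = train_model(loc_train, loc_val, cfg.localizer, loc_cfg)
    if verbose:
        print(f"localizer: best val loss {localizer.best_val_loss:.3f} "
              f"at epoch {localizer.best_epoch}")

    # stage 2: multiclass segmenter on cord crops, patch grid, batch 8
    seg_cfg = TrainConfig(
        lr=0.001,
        max_epochs=cfg.seg_epochs,
        patience=min(cfg.patience, cfg.seg_epochs),
        batch_size=8,
        patch_size=cfg.seg_patch,
        stride=cfg.seg_stride,
        seed=seed + 303,
    )
    seg_train = [
        _segmenter_sample(prepared[s], preproc, cfg.bbox_margin_mm)
        for s in split.train
    ]
    seg_val = [
        _segmenter_sample(prepared[s], preproc, cfg.bbox_margin_mm)
        for s in split.validation
    ]
    segmenter = train_model(seg_train, seg_val, cfg.segmenter, seg_cfg)
    if verbose:
        print(f"segmenter: best val loss {segmenter.best_val_loss:.3f} "
              f"at epoch {segmenter.best_epoch}")

    # held-out evaluation through the full cascade, standard space
    cascade_cfg = CascadeConfig(
        localizer_patch=cfg.grid_shape,
        segmenter_patch=cfg.seg_patch,
        segmenter_stride=cfg.seg_stride,
        bbox_margin_mm=cfg.bbox_margin_mm,
    )
    frames = []
    loc_dices, inclusions, failures = [], [], 0
    for sid in split.test:
        prep = prepared[sid]
        try:
            res = run_cascade(
                prep.record, localizer.model, segmenter.model, preproc, cascade_cfg
            )
        except LocalizationFailure:
            failures += 1
            continue
        loc_dices.append(dice_score(res.cord_mask_std, prep.tube_std))
        inclusions.append(bbox_inclusion(prep.labels_std[3], res.bbox)[0])
        frames.append(
            evaluate_subject(
                res.std_labels,
                prep.labels_std,
                preproc.target_spacing,
                subject_id=sid,
                cfg=MetricsConfig(),
            )
        )
    per_subject = pd.concat(frames, ignore_index=True)

    def _rate(col, structure):
        sub = per_subject[per_subject["structure"] == structure][col].dropna()
        return float(sub.mean()) if len(sub) else None

    results = {
        "n_test": len(split.test),
        "localization_failures": failures,
        "localization_dice": float(np.mean(loc_dices)),
        "bbox_inclusion_rate": float(np.mean(inclusions)),
        "dice": {
            s: _cohort_dice(per_subject, s, restricted=False)
            for s in ("whole", "tumor", "cavity", "edema")
        },
        "dice_restricted": {
            s: _cohort_dice(per_subject, s, restricted=True)
            for s in ("cavity", "edema")
        },
        "tp_rate": {s: _rate("true_positive", s) for s in ("whole", "tumor", "cavity", "edema")},
        "fp_rate": {s: _rate("false_positive", s) for s in ("cavity", "edema")},
        "rvd": {s: _rate("rvd", s) for s in ("whole", "tumor")},
    }
    return ToyStudyResult(
        results=results,
        per_subject=per_subject,
        localizer=localizer,
        segmenter=segmenter,
        split=split,
        config=cfg,
    )
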