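"""Two-step cascaded inference.

Step 1 localizes the spinal cord on the standard-space T2w volume and
derives a 3D bounding box from the predicted mask.  Step 2 crops both
contrasts to that box, re-normalizes, runs the multiclass segmenter over
a stride grid of patches, stitches overlapping predictions by averaging,
postprocesses, and maps the result back to the native scan grid.

A single-step variant (the segmenter applied to the whole standard grid,
no localization crop) is provided for the cascaded-vs-single-step
comparison experiment.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, LocalizationFailure
from .imgio import (
    ImageVolume,
    LabelVolume,
    PreprocConfig,
    SpatialTransformRecord,
    invert_to_native,
    preprocess_to_standard,
    zscore_normalize,
)
from .net3d import UNet3D
from .postproc import PostprocConfig, binarize, postprocess_labels
from .train import extract_patches, pad_to_shape


@dataclass
class BoundingBox3D:
    """Half-open voxel-index box ``[lo, hi)`` in standard space."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    margin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass
class CascadeConfig:
    localizer_patch: tuple[int, int, int] = (512, 256, 32)
    segmenter_patch: tuple[int, int, int] = (128, 128, 32)
    segmenter_stride: tuple[int, int, int] = (64, 64, 32)
    bbox_margin_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    localizer_threshold: float = 0.5
    largest_component_only: bool = False

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.bbox_margin_mm):
            raise ValueError("bbox margins must be non-negative")


# ---------------------------------------------------------------------------
# Patch stitching


def stitch_patches(patch_preds, origins, out_shape) -> np.ndarray:
    """Reassemble overlapping patch predictions by overlap averaging.

    Each voxel receives the arithmetic mean of every patch value covering
    it; a voxel covered by no patch is a consistency error.
    """
    patch_preds = [np.asarray(p, dtype=np.float32) for p in patch_preds]
    lead = patch_preds[0].shape[:-3]
    accum = np.zeros(lead + tuple(out_shape), dtype=np.float32)
    counts = np.zeros(tuple(out_shape), dtype=np.float32)
    for pred, origin in zip(patch_preds, origins):
        sl = tuple(
            slice(o, o + s) for o, s in zip(origin, pred.shape[-3:])
        )
        accum[(...,) + sl] += pred
        counts[sl] += 1.0
    if (counts == 0).any():
        raise ConsistencyError("patch grid leaves voxels uncovered")
    return accum / counts


def sliding_window_predict(
    model: UNet3D, vol: np.ndarray, patch_size, stride
) -> np.ndarray:
    """Stitched inference of ``model`` over a ``(C, X, Y, Z)`` volume.

    The volume is zero-padded (high side) up to the patch size if needed;
    the output is cropped back to the input grid.
    """
    vol = np.asarray(vol, dtype=np.float32)
    padded, orig_shape = pad_to_shape(vol, patch_size)
    patches = extract_patches(padded, patch_size, stride)
    preds = [model.forward(p[None], training=False)[0] for p, _ in patches]
    origins = [o for _, o in patches]
    stitched = stitch_patches(preds, origins, padded.shape[-3:])
    sl = tuple(slice(0, n) for n in orig_shape)
    return stitched[(...,) + sl]


# ---------------------------------------------------------------------------
# Step 1: localization


def localize_cord(t2w_std: np.ndarray, localizer: UNet3D, cfg: CascadeConfig) -> np.ndarray:
    """Predict the binary cord tube on a standard-space T2w array."""
    t2w_std = np.asarray(t2w_std, dtype=np.float32)
    pred = sliding_window_predict(
        localizer, t2w_std[None], cfg.localizer_patch, cfg.localizer_patch
    )[0]
    mask = binarize(pred, cfg.localizer_threshold)
    if cfg.largest_component_only and mask.any():
        labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        if n > 1:
            counts = np.bincount(labeled.ravel())
            counts[0] = 0
            mask = (labeled == int(counts.argmax())).astype(np.uint8)
    if not mask.any():
        raise LocalizationFailure("localizer produced an empty cord mask")
    return mask


def mask_to_bbox(mask: np.ndarray, margin_mm, spacing) -> BoundingBox3D:
    """Tightest box around the mask, dilated by ``margin_mm`` (rounded up
    to voxels) and clipped to the volume bounds."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("cannot derive a bounding box from an empty mask")
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    dil = np.array(
        [int(np.ceil(m / s)) for m, s in zip(margin_mm, spacing)], dtype=int
    )
    lo = np.maximum(lo - dil, 0)
    hi = np.minimum(hi + dil, mask.shape)
    return BoundingBox3D(tuple(int(v) for v in lo), tuple(int(v) for v in hi), tuple(margin_mm))


# ---------------------------------------------------------------------------
# Step 2: segmentation


def segment_tumor(
    crop_gd_t1w: np.ndarray, crop_t2w: np.ndarray, segmenter: UNet3D, cfg: CascadeConfig
) -> np.ndarray:
    """4-channel soft prediction over aligned, normalized crops."""
    crop_gd_t1w = np.asarray(crop_gd_t1w, dtype=np.float32)
    crop_t2w = np.asarray(crop_t2w, dtype=np.float32)
    if crop_gd_t1w.shape != crop_t2w.shape:
        raise ConsistencyError(
            f"misaligned crops: {crop_gd_t1w.shape} vs {crop_t2w.shape}"
        )
    stacked = np.stack([crop_gd_t1w, crop_t2w])
    return sliding_window_predict(
        segmenter, stacked, cfg.segmenter_patch, cfg.segmenter_stride
    )


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class CascadeResult:
    subject_id: str
    native_labels: LabelVolume
    std_labels: np.ndarray  # (4, crop grid) binary, standard space
    bbox: BoundingBox3D | None
    cord_mask_std: np.ndarray | None
    record: SpatialTransformRecord
    log: dict = field(default_factory=dict)


def _preprocess_pair(subject, preproc_cfg: PreprocConfig):
    t2_std, record = preprocess_to_standard(subject.t2w, preproc_cfg, interp="linear")
    t1_std, _ = preprocess_to_standard(subject.gd_t1w, preproc_cfg, interp="linear")
    return t1_std, t2_std, record


def run_cascade(
    subject,
    localizer: UNet3D,
    segmenter: UNet3D,
    preproc_cfg: PreprocConfig | None = None,
    cascade_cfg: CascadeConfig | None = None,
    postproc_cfg: PostprocConfig | None = None,
) -> CascadeResult:
    """Full two-step pipeline for one subject, native-space output.

    Composes preprocessing, cord localization, cropping, patchwise
    multiclass segmentation with overlap-average stitching,
    postprocessing, and inversion to the native grid.  Stage errors are
    re-raised with the subject id attached.
    """
    preproc_cfg = preproc_cfg or PreprocConfig()
    cascade_cfg = cascade_cfg or CascadeConfig()
    postproc_cfg = postproc_cfg or PostprocConfig()
    log: dict = {"subject_id": subject.subject_id, "timings_s": {}}
    try:
        t0 = time.perf_counter()
        t1_std, t2_std, record = _preprocess_pair(subject, preproc_cfg)
        log["timings_s"]["preprocess"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        cord_mask = localize_cord(t2_std.data, localizer, cascade_cfg)
        log["timings_s"]["localize"] = time.perf_counter() - t0
        log["cord_mask_voxels"] = int(cord_mask.sum())

        bbox = mask_to_bbox(
            cord_mask, cascade_cfg.bbox_margin_mm, preproc_cfg.target_spacing
        )
        log["bbox"] = {"lo": bbox.lo, "hi": bbox.hi}

        t0 = time.perf_counter()
        sl = bbox.slices()
        crop_t1 = zscore_normalize(ImageVolume(t1_std.data[sl], t1_std.spacing)).data
        crop_t2 = zscore_normalize(ImageVolume(t2_std.data[sl], t2_std.spacing)).data
        soft = segment_tumor(crop_t1, crop_t2, segmenter, cascade_cfg)
        log["timings_s"]["segment"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        post, post_log = postprocess_labels(
            soft, preproc_cfg.target_spacing, postproc_cfg
        )
        log["postprocess"] = post_log
        std_labels = np.zeros((4,) + tuple(preproc_cfg.crop_shape), dtype=np.uint8)
        std_labels[(...,) + sl] = post
        native = invert_to_native(
            LabelVolume(std_labels, preproc_cfg.target_spacing), record
        )
        log["timings_s"]["postprocess_invert"] = time.perf_counter() - t0
    except Exception as exc:
        exc.args = (f"[{subject.subject_id}] " + " ".join(str(a) for a in exc.args),)
        raise
    return CascadeResult(
        subject_id=subject.subject_id,
        native_labels=native,
        std_labels=std_labels,
        bbox=bbox,
        cord_mask_std=cord_mask,
        record=record,
        log=log,
    )


def run_single_step(
    subject,
    segmenter: UNet3D,
    preproc_cfg: PreprocConfig | None = None,
    cascade_cfg: CascadeConfig | None = None,
    postproc_cfg: PostprocConfig | None = None,
) -> CascadeResult:
    """Segmenter applied to the full standard grid (no localization crop);
    the comparison arm for the cascaded-vs-single-step experiment."""
    preproc_cfg = preproc_cfg or PreprocConfig()
    cascade_cfg = cascade_cfg or CascadeConfig()
    postproc_cfg = postproc_cfg or PostprocConfig()
    t1_std, t2_std, record = _preprocess_pair(subject, preproc_cfg)
    soft = segment_tumor(t1_std.data, t2_std.data, segmenter, cascade_cfg)
    post, post_log = postprocess_labels(soft, preproc_cfg.target_spacing, postproc_cfg)
    native = invert_to_native(LabelVolume(post, preproc_cfg.target_spacing), record)
    return CascadeResult(
        subject_id=subject.subject_id,
        native_labels=native,
        std_labels=post,
        bbox=None,
        cord_mask_std=None,
        record=record,
        log={"subject_id": subject.subject_id, "postprocess": post_log},
    )


def run_cohort(subjects, localizer, segmenter, **kwargs):
    """Run the cascade over a cohort; localization failures are flagged
    per subject instead of aborting the run."""
    results, failures = [], []
    for subject in subjects:
        try:
            results.append(run_cascade(subject, localizer, segmenter, **kwargs))
        except LocalizationFailure as exc:
            failures.append({"subject_id": subject.subject_id, "error": str(exc)})
    return results, failures
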