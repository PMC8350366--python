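"""Prediction cleanup: threshold, fill holes, drop small components.

The chain runs in the fixed order binarize -> fill holes -> remove
components below a physical volume floor (0.2 cm^3 for tumor and whole
lesion, 0.5 cm^3 for cavity and edema).  Channels are processed
independently; in particular the whole-lesion channel is *not*
recomputed as the union of the structure channels afterwards — any
discrepancy is reported in the log rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import LABEL_CHANNELS

_DEFAULT_MIN_VOLUME = {"tumor": 0.2, "cavity": 0.5, "edema": 0.5, "whole": 0.2}


@dataclass
class PostprocConfig:
    threshold: float = 0.5
    min_volume_cm3: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIN_VOLUME)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if any(v < 0 for v in self.min_volume_cm3.values()):
            raise ValueError("minimum volumes must be non-negative")


#: 26-neighborhood for foreground components
_FG_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


def binarize(soft: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a soft map; ties (exactly at threshold) go to foreground."""
    return (np.asarray(soft) >= threshold).astype(np.uint8)


def fill_holes(binary: np.ndarray) -> np.ndarray:
    """Fill 3D background cavities not connected to the volume border
    (6-neighborhood background connectivity)."""
    return ndimage.binary_fill_holes(np.asarray(binary) > 0).astype(np.uint8)


def remove_small_components(
    binary: np.ndarray, min_volume_cm3: float, spacing
) -> np.ndarray:
    """Delete 26-connected components with physical volume strictly below
    ``min_volume_cm3``; components exactly at the floor are kept."""
    binary = np.asarray(binary) > 0
    if not binary.any() or min_volume_cm3 <= 0:
        return binary.astype(np.uint8)
    voxel_mm3 = float(np.prod(spacing))
    labeled, n = ndimage.label(binary, structure=_FG_STRUCTURE)
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    keep = counts * voxel_mm3 >= min_volume_cm3 * 1000.0
    keep[0] = False
    return keep[labeled].astype(np.uint8)


def postprocess_channel(
    soft: np.ndarray, spacing, min_volume_cm3: float, threshold: float = 0.5
) -> np.ndarray:
    out = binarize(soft, threshold)
    out = fill_holes(out)
    return remove_small_components(out, min_volume_cm3, spacing)


def postprocess_labels(
    soft4: np.ndarray, spacing, cfg: PostprocConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Postprocess a 4-channel soft prediction (tumor, cavity, edema, whole).

    Returns the binary channels and a log dict that includes the voxel
    count on which the whole channel disagrees with the union of the
    three structure channels (reported, never reconciled).
    """
    cfg = cfg or PostprocConfig()
    soft4 = np.asarray(soft4)
    if soft4.shape[0] != len(LABEL_CHANNELS):
        raise ValueError(f"expected {len(LABEL_CHANNELS)} channels, got {soft4.shape[0]}")
    out = np.stack(
        [
            postprocess_channel(
                soft4[i], spacing, cfg.min_volume_cm3[name], cfg.threshold
            )
            for i, name in enumerate(LABEL_CHANNELS)
        ]
    )
    union = (out[0] | out[1] | out[2]).astype(np.uint8)
    log = {
        "voxels_per_channel": {
            name: int(out[i].sum()) for i, name in enumerate(LABEL_CHANNELS)
        },
        "whole_vs_union_mismatch_voxels": int(np.count_nonzero(out[3] != union)),
    }
    return out, log
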