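"""NIfTI I/O and deterministic spatial/intensity preprocessing.

All volumes in this package follow a single axis convention:

* axis 0 — superior-inferior (S-I), ascending index toward superior
* axis 1 — anterior-posterior (A-P), ascending toward anterior
* axis 2 — right-left (R-L), ascending toward the subject's right

Voxel indices are 0-based and boxes are half-open ``[lo, hi)``.  Voxel
centers sit at ``(i + 0.5) * spacing`` millimetres from the volume corner,
so a volume of ``n`` voxels at spacing ``s`` has physical extent ``n * s``.

The preprocessing chain applied before either network is the one used at
inference and training time alike: resample to the standard resolution of
1 x 1 x 2 mm (S-I, A-P, R-L), center crop-or-pad to a fixed grid, and
z-score the intensities.  Every spatial step is recorded in a
:class:`SpatialTransformRecord` so that predictions can be mapped back
onto the native scan grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, DegenerateInputError, FormatError

#: channel order used for every multi-channel label volume in the package
LABEL_CHANNELS = ("tumor", "cavity", "edema", "whole")


@dataclass
class ImageVolume:
    """A 3D scalar image with per-axis physical spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Extent in mm per axis (voxel count times spacing)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class LabelVolume:
    """Aligned binary masks, channel order ``(tumor, cavity, edema, whole)``.

    ``whole`` is by construction the voxelwise union of the other three;
    :meth:`from_components` enforces it, and postprocessing may later break
    it (the discrepancy is then logged, not silently reconciled).
    """

    data: np.ndarray  # (4, SI, AP, RL), values in {0, 1}
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != len(LABEL_CHANNELS):
            raise ValueError(f"expected (4, X, Y, Z) label data, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @classmethod
    def from_components(cls, tumor, cavity, edema, spacing) -> "LabelVolume":
        tumor = np.asarray(tumor, dtype=np.uint8)
        cavity = np.asarray(cavity, dtype=np.uint8)
        edema = np.asarray(edema, dtype=np.uint8)
        whole = ((tumor | cavity | edema) > 0).astype(np.uint8)
        return cls(np.stack([tumor, cavity, edema, whole]), spacing)

    def channel(self, name: str) -> np.ndarray:
        return self.data[LABEL_CHANNELS.index(name)]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class PreprocConfig:
    """Standard-space geometry of the pipeline.

    The clinical defaults are a 1 x 1 x 2 mm grid cropped (or zero-padded)
    to 512 x 256 x 32 voxels, i.e. a 51.2 x 25.6 x 6.4 cm field of view
    centered on the scan.
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    crop_shape: tuple[int, int, int] = (512, 256, 32)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if any(n <= 0 for n in self.crop_shape):
            raise ValueError("crop_shape must be positive")

    def crop_extent_mm(self) -> tuple[float, float, float]:
        """Physical extent of the standard crop per axis, in mm."""
        return tuple(n * s for n, s in zip(self.crop_shape, self.target_spacing))


@dataclass
class SpatialTransformRecord:
    """Invertible description of resample + crop-or-pad for one subject.

    ``offset[a]`` is the index in the resampled grid of the cropped
    window's first voxel on axis ``a``; it is negative when the axis was
    padded instead of cropped.
    """

    native_shape: tuple[int, int, int]
    native_spacing: tuple[float, float, float]
    std_spacing: tuple[float, float, float]
    resampled_shape: tuple[int, int, int]
    crop_shape: tuple[int, int, int]
    offset: tuple[int, int, int] = field(default=(0, 0, 0))

    def is_identity(self) -> bool:
        return (
            self.native_shape == self.crop_shape
            and tuple(self.native_spacing) == tuple(self.std_spacing)
            and self.offset == (0, 0, 0)
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _canonical_to_pipeline(data: np.ndarray) -> np.ndarray:
    # nibabel canonical is RAS+ (R-L, P-A, I-S ascending); the pipeline wants
    # (S-I, A-P, R-L) axis order, which is a pure transpose of RAS axes.
    return np.transpose(data, (2, 1, 0))


def read_nifti(path) -> ImageVolume:
    """Read a scalar NIfTI volume, reorienting to the pipeline convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(_canonical_to_pipeline(data), (zooms[2], zooms[1], zooms[0]))


def write_nifti(vol: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as a canonically oriented NIfTI file."""
    data = np.transpose(np.asarray(vol.data), (2, 1, 0))
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_label_volume(path) -> LabelVolume:
    """Read a 4-channel label NIfTI (channels stored on the 4th axis)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != len(LABEL_CHANNELS):
        raise FormatError(f"{path}: expected (X, Y, Z, 4) labels, got {data.shape}")
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(data, (3, 2, 1, 0)).astype(np.uint8)
    return LabelVolume(data, (zooms[2], zooms[1], zooms[0]))


def write_label_volume(labels: LabelVolume, path) -> None:
    data = np.transpose(np.asarray(labels.data, dtype=np.uint8), (3, 2, 1, 0))
    affine = np.diag([labels.spacing[2], labels.spacing[1], labels.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Resampling


def _resampled_shape(shape, spacing, target_spacing) -> tuple[int, ...]:
    # grid size = round(extent / target spacing), round-half-to-even
    return tuple(
        max(1, int(np.round(n * s / t)))
        for n, s, t in zip(shape, spacing, target_spacing)
    )


def resample(vol: ImageVolume, target_spacing, interp: str = "linear") -> ImageVolume:
    """Resample to ``target_spacing`` preserving the physical extent.

    ``interp`` is ``"linear"`` for images and ``"nearest"`` for masks
    (nearest keeps binary masks binary).  Voxel centers are aligned so the
    corner of the physical volume is shared between grids.
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    if tuple(vol.spacing) == target_spacing:
        return ImageVolume(vol.data.copy(), vol.spacing)
    out_shape = _resampled_shape(vol.shape, vol.spacing, target_spacing)
    scale = np.array([t / s for s, t in zip(vol.spacing, target_spacing)])
    order = {"linear": 1, "nearest": 0}[interp]
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=np.float32),
        np.diag(scale),
        offset=0.5 * scale - 0.5,
        output_shape=out_shape,
        order=order,
        mode="nearest",
    )
    if order == 0:
        out = np.rint(out)
    return ImageVolume(out, target_spacing)


# ---------------------------------------------------------------------------
# Crop / pad


def _crop_offset(n_in: int, n_out: int) -> int:
    """Start index (negative = padding) of the centered window.

    Odd differences put the extra cropped/padded voxel on the high-index
    side.
    """
    if n_in >= n_out:
        return (n_in - n_out) // 2
    return -((n_out - n_in) // 2)


def _apply_crop_or_pad(data: np.ndarray, out_shape, offsets) -> np.ndarray:
    out = np.zeros(tuple(out_shape), dtype=data.dtype)
    src = []
    dst = []
    for n_in, n_out, o in zip(data.shape, out_shape, offsets):
        lo_src = max(o, 0)
        lo_dst = max(-o, 0)
        length = min(n_in - lo_src, n_out - lo_dst)
        src.append(slice(lo_src, lo_src + length))
        dst.append(slice(lo_dst, lo_dst + length))
    out[tuple(dst)] = data[tuple(src)]
    return out


def center_crop_or_pad(
    vol: ImageVolume, crop_shape
) -> tuple[ImageVolume, SpatialTransformRecord]:
    """Center crop axes larger than ``crop_shape``, zero-pad smaller ones."""
    crop_shape = tuple(int(n) for n in crop_shape)
    offsets = tuple(_crop_offset(n, m) for n, m in zip(vol.shape, crop_shape))
    out = _apply_crop_or_pad(np.asarray(vol.data), crop_shape, offsets)
    record = SpatialTransformRecord(
        native_shape=vol.shape,
        native_spacing=vol.spacing,
        std_spacing=vol.spacing,
        resampled_shape=vol.shape,
        crop_shape=crop_shape,
        offset=offsets,
    )
    return ImageVolume(out, vol.spacing), record


# ---------------------------------------------------------------------------
# Intensity normalization


def zscore_normalize(vol: ImageVolume) -> ImageVolume:
    """Subtract the mean intensity and divide by the standard deviation."""
    data = np.asarray(vol.data, dtype=np.float32)
    sd = float(data.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("constant-intensity volume cannot be z-scored")
    return ImageVolume((data - data.mean()) / sd, vol.spacing)


# ---------------------------------------------------------------------------
# Full standard-space preprocessing and its inverse


def preprocess_to_standard(
    vol: ImageVolume, cfg: PreprocConfig, interp: str = "linear", normalize: bool = True
) -> tuple[ImageVolume, SpatialTransformRecord]:
    """Resample to standard spacing, center crop-or-pad, optionally z-score."""
    res = resample(vol, cfg.target_spacing, interp=interp)
    cropped, rec = center_crop_or_pad(res, cfg.crop_shape)
    record = SpatialTransformRecord(
        native_shape=vol.shape,
        native_spacing=vol.spacing,
        std_spacing=cfg.target_spacing,
        resampled_shape=res.shape,
        crop_shape=tuple(cfg.crop_shape),
        offset=rec.offset,
    )
    if normalize:
        cropped = zscore_normalize(cropped)
    return cropped, record


def invert_to_native(pred: LabelVolume, record: SpatialTransformRecord) -> LabelVolume:
    """Map a standard-space label prediction back to the native grid.

    Undoes the center crop-or-pad (embedding the crop into the resampled
    grid) and then resamples to the native spacing with nearest
    interpolation so labels stay binary.
    """
    if tuple(pred.shape) != tuple(record.crop_shape):
        raise ConsistencyError(
            f"prediction shape {pred.shape} does not match record crop "
            f"shape {record.crop_shape}"
        )
    out_channels = []
    for ch in pred.data:
        # embed crop into the resampled grid: inverse of _apply_crop_or_pad
        inv_offsets = tuple(-o for o in record.offset)
        emb = _apply_crop_or_pad(
            np.asarray(ch, dtype=np.uint8), record.resampled_shape, inv_offsets
        )
        if (
            tuple(record.std_spacing) == tuple(record.native_spacing)
            and tuple(record.resampled_shape) == tuple(record.native_shape)
        ):
            out_channels.append(emb)
            continue
        scale = np.array(
            [n / s for n, s in zip(record.native_spacing, record.std_spacing)]
        )
        nat = ndimage.affine_transform(
            emb.astype(np.float32),
            np.diag(scale),
            offset=0.5 * scale - 0.5,
            output_shape=record.native_shape,
            order=0,
            mode="nearest",
        )
        out_channels.append(np.rint(nat).astype(np.uint8))
    return LabelVolume(np.stack(out_channels), record.native_spacing)
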