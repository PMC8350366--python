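"""Synthetic two-contrast spinal-cord tumor phantoms.

The generator emulates the statistical structure of a clinical
intramedullary spinal-cord tumor (IMSCT) cohort so the full
train / infer / postprocess / evaluate loop can be exercised without any
patient data:

* sagittal volumes with heterogeneous native resolution — in-plane
  spacing drawn uniformly from [0.34, 1.33] mm and slice thickness from
  [1.5, 5.2] mm;
* a curved tubular cord (13 mm diameter) with a CSF sheath, plus the
  30 mm-diameter localization tube used as ground truth for the cord
  localizer;
* tumor / edema / cavity components rasterized as ellipsoids deformed
  along the cord centerline, whose two-contrast intensity rules follow
  the qualitative radiology: on T2w, cavity > edema > tumor >= cord >
  background; on Gd-enhanced T1w the tumor enhancement depends on tumor
  type (hemangioblastoma strong, ependymoma moderate, astrocytoma none or
  moderate with equal probability) while cavities never enhance;
* cohort class imbalance: 67% of subjects carry a cavity, 51% edema,
  and tumor types in proportions 101 : 122 : 120
  (astrocytoma : ependymoma : hemangioblastoma).

All geometry is computed in physical millimetres on the subject's native
grid, so downstream resampling is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError
from .imgio import (
    ImageVolume,
    LabelVolume,
    read_label_volume,
    read_nifti,
    write_label_volume,
    write_nifti,
)

TUMOR_TYPES = ("astrocytoma", "ependymoma", "hemangioblastoma")
#: cohort proportions of the three tumor types
TUMOR_TYPE_WEIGHTS = (101, 122, 120)

CORD_DIAMETER_MM = 13.0
TUBE_DIAMETER_MM = 30.0
CSF_THICKNESS_MM = 3.0

#: reference spacing used to interpret ``PhantomSpec.grid_shape`` as a
#: physical extent (matches the pipeline's standard space)
REFERENCE_SPACING = (1.0, 1.0, 2.0)


def default_intensity_table() -> dict[tuple[str, str], float]:
    """Noise-free mean intensity per (contrast, tissue), arbitrary units.

    T2w ordering: cavity > edema > tumor >= cord > background, with CSF
    bright (fluid); Gd-T1w: CSF/cavity dark, cord/tumor intermediate, and
    tumor enhancement added separately per tumor type.
    """
    return {
        ("t2w", "background"): 50.0,
        ("t2w", "cord"): 100.0,
        ("t2w", "csf"): 400.0,
        ("t2w", "tumor"): 150.0,
        ("t2w", "edema"): 250.0,
        ("t2w", "cavity"): 450.0,
        ("gd_t1w", "background"): 50.0,
        ("gd_t1w", "cord"): 200.0,
        ("gd_t1w", "csf"): 100.0,
        ("gd_t1w", "tumor"): 200.0,
        ("gd_t1w", "edema"): 180.0,
        ("gd_t1w", "cavity"): 100.0,
    }


#: Gd-T1w intensity added to the tumor mean, per enhancement level
ENHANCEMENT_DELTA = {"none": 0.0, "moderate": 150.0, "strong": 300.0}


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    ``grid_shape`` is the nominal voxel grid at the reference spacing of
    (1, 1, 2) mm; it fixes the physical extent of every subject.  Each
    subject then receives its own native grid from per-subject spacing
    draws, so phantoms arrive at heterogeneous resolution like the
    clinical scans they emulate.
    """

    grid_shape: tuple[int, int, int] = (96, 48, 24)
    in_plane_range: tuple[float, float] = (0.34, 1.33)
    slice_thickness_range: tuple[float, float] = (1.5, 5.2)
    tumor_type: str | None = None  # None -> draw from TUMOR_TYPE_WEIGHTS
    p_cavity: float = 0.67
    p_edema: float = 0.51
    intensity_table: dict = field(default_factory=default_intensity_table)
    noise_sd: float = 10.0
    curvature_amp: float = 4.0  # mm
    n_tumor_blobs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_cavity <= 1.0 and 0.0 <= self.p_edema <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.tumor_type is not None and self.tumor_type not in TUMOR_TYPES:
            raise ValueError(f"unknown tumor type {self.tumor_type!r}")
        t2 = {k[1]: v for k, v in self.intensity_table.items() if k[0] == "t2w"}
        order = (
            t2["cavity"] > t2["edema"] > t2["tumor"] >= t2["cord"] > t2["background"]
        )
        if not order:
            raise ValueError(
                "T2w intensity table must satisfy cavity > edema > tumor >= "
                "cord > background"
            )

    def physical_extent(self) -> tuple[float, float, float]:
        return tuple(
            n * s for n, s in zip(self.grid_shape, REFERENCE_SPACING)
        )


@dataclass
class SubjectRecord:
    """One synthetic case: both contrasts, labels, cord tube and metadata."""

    subject_id: str
    gd_t1w: ImageVolume
    t2w: ImageVolume
    labels: LabelVolume
    cord_mask: ImageVolume  # 30 mm-diameter tube around the centerline
    metadata: dict

    def __post_init__(self) -> None:
        shapes = {
            self.gd_t1w.shape,
            self.t2w.shape,
            self.labels.shape,
            self.cord_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"misaligned volumes in subject record: {shapes}")


# ---------------------------------------------------------------------------
# Geometry


def _centerline(grid_shape, spacing, curvature_amp, rng):
    """Smooth centerline through the full S-I extent; mm coordinates."""
    n0 = grid_shape[0]
    extent = [n * s for n, s in zip(grid_shape, spacing)]
    s = (np.arange(n0) + 0.5) * spacing[0]
    phase_ap, phase_rl = rng.uniform(0, 2 * np.pi, size=2)
    n_periods = rng.uniform(0.8, 1.6)
    # keep the 30 mm tube inside the field of view
    amp_ap = min(curvature_amp, max(0.0, extent[1] / 2 - TUBE_DIAMETER_MM / 2))
    amp_rl = min(0.3 * curvature_amp, max(0.0, extent[2] / 2 - TUBE_DIAMETER_MM / 2))
    cy = extent[1] / 2 + amp_ap * np.sin(2 * np.pi * n_periods * s / extent[0] + phase_ap)
    cz = extent[2] / 2 + amp_rl * np.sin(2 * np.pi * n_periods * s / extent[0] + phase_rl)
    return np.stack([s, cy, cz], axis=1)


def _tube_mask(grid_shape, spacing, centerline, radius_mm):
    """Binary tube of given radius around the centerline (in-plane distance)."""
    y = (np.arange(grid_shape[1]) + 0.5) * spacing[1]
    z = (np.arange(grid_shape[2]) + 0.5) * spacing[2]
    dy2 = (y[None, :] - centerline[:, 1:2]) ** 2  # (n0, n1)
    dz2 = (z[None, :] - centerline[:, 2:3]) ** 2  # (n0, n2)
    return (dy2[:, :, None] + dz2[:, None, :]) <= radius_mm**2


def rasterize_cord(grid_shape, spacing, curvature_amp, seed):
    """Rasterize the cord and its 30 mm localization tube.

    Returns ``(centerline_mm, cord_mask, tube_mask)`` where the centerline
    is an ``(n0, 3)`` array of physical coordinates, ``cord_mask`` is the
    ~13 mm-diameter cord and ``tube_mask`` the 30 mm-diameter tube that
    strictly contains it.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")
    extent = [n * s for n, s in zip(grid_shape, spacing)]
    min_transverse = CORD_DIAMETER_MM + 2 * CSF_THICKNESS_MM
    if extent[1] < min_transverse or extent[2] < min_transverse:
        raise GeometryError(
            f"transverse extent {extent[1]:.1f} x {extent[2]:.1f} mm too small "
            f"for a {CORD_DIAMETER_MM:.0f} mm cord with CSF sheath"
        )
    rng = np.random.default_rng(seed)
    centerline = _centerline(grid_shape, spacing, curvature_amp, rng)
    cord = _tube_mask(grid_shape, spacing, centerline, CORD_DIAMETER_MM / 2)
    tube = _tube_mask(grid_shape, spacing, centerline, TUBE_DIAMETER_MM / 2)
    return centerline, cord, tube


def _ellipsoid_along_cord(grid_shape, spacing, centerline, center_s, semi_len, semi_rad):
    """Ellipsoid deformed along the centerline: per-slice circular cross
    sections centered on the cord axis, with S-I semi-axis ``semi_len``."""
    s = centerline[:, 0]
    axial = ((s - center_s) / semi_len) ** 2  # (n0,)
    y = (np.arange(grid_shape[1]) + 0.5) * spacing[1]
    z = (np.arange(grid_shape[2]) + 0.5) * spacing[2]
    dy2 = (y[None, :] - centerline[:, 1:2]) ** 2
    dz2 = (z[None, :] - centerline[:, 2:3]) ** 2
    radial = (dy2[:, :, None] + dz2[:, None, :]) / semi_rad**2
    return (axial[:, None, None] + radial) <= 1.0


# ---------------------------------------------------------------------------
# Subject generation


def _draw_components(rng, spec, centerline, cord, grid_shape, spacing, want_cavity, want_edema):
    """Draw and rasterize tumor (+ optional cavity/edema), all within the cord."""
    L = grid_shape[0] * spacing[0]
    for _ in range(20):
        n_blobs = spec.n_tumor_blobs
        tumor = np.zeros(grid_shape, dtype=bool)
        centers, lengths = [], []
        for _b in range(n_blobs):
            l_t = float(np.clip(rng.lognormal(np.log(12.0), 0.3), 6.0, 0.25 * L))
            s_t = rng.uniform(0.3 * L, 0.7 * L)
            r_t = rng.uniform(3.5, 6.0)
            tumor |= _ellipsoid_along_cord(
                grid_shape, spacing, centerline, s_t, l_t, r_t
            )
            centers.append(s_t)
            lengths.append(l_t)
        tumor &= cord
        if not tumor.any():
            continue
        s_t, l_t = centers[0], lengths[0]

        edema = np.zeros(grid_shape, dtype=bool)
        if want_edema:
            # centered on a tumor pole so it overlaps, then carved back:
            # the remainder necessarily touches the tumor
            sign = rng.choice([-1.0, 1.0])
            l_e = float(np.clip(rng.lognormal(np.log(10.0), 0.3), 5.0, 0.2 * L))
            s_e = float(np.clip(s_t + sign * l_t, 0.1 * L, 0.9 * L))
            r_e = rng.uniform(3.5, 6.0)
            edema = _ellipsoid_along_cord(grid_shape, spacing, centerline, s_e, l_e, r_e)
            edema &= cord
            edema &= ~tumor
            if not edema.any():
                continue

        cavity = np.zeros(grid_shape, dtype=bool)
        if want_cavity:
            # along the cord, possibly separated from the tumor by a gap
            sign = rng.choice([-1.0, 1.0])
            l_c = float(np.clip(rng.lognormal(np.log(14.0), 0.3), 6.0, 0.25 * L))
            gap = rng.uniform(-5.0, 15.0)
            s_c = float(np.clip(s_t + sign * (l_t + gap + l_c), 0.08 * L, 0.92 * L))
            r_c = rng.uniform(3.5, 6.0)
            cavity = _ellipsoid_along_cord(grid_shape, spacing, centerline, s_c, l_c, r_c)
            cavity &= cord
            cavity &= ~tumor
            cavity &= ~edema
            if not cavity.any():
                continue
        return tumor, cavity, edema
    raise GeometryError("could not place requested lesion components in the cord")


def generate_subject(spec: PhantomSpec, subject_seed: int) -> SubjectRecord:
    """Generate one synthetic subject, deterministic in ``(spec, subject_seed)``."""
    rng = np.random.default_rng([int(spec.seed), int(subject_seed)])

    sp_in = rng.uniform(*spec.in_plane_range)
    sp_sl = rng.uniform(*spec.slice_thickness_range)
    spacing = (float(sp_in), float(sp_in), float(sp_sl))
    extent = spec.physical_extent()
    grid_shape = tuple(max(1, int(np.round(e / s))) for e, s in zip(extent, spacing))

    geom_seed = int(rng.integers(0, 2**31 - 1))
    centerline, cord, tube = rasterize_cord(
        grid_shape, spacing, spec.curvature_amp, geom_seed
    )
    csf = _tube_mask(
        grid_shape, spacing, centerline, CORD_DIAMETER_MM / 2 + CSF_THICKNESS_MM
    )

    tumor_type = spec.tumor_type
    if tumor_type is None:
        w = np.asarray(TUMOR_TYPE_WEIGHTS, dtype=float)
        tumor_type = str(rng.choice(TUMOR_TYPES, p=w / w.sum()))
    if tumor_type == "hemangioblastoma":
        enhancement = "strong"
    elif tumor_type == "ependymoma":
        enhancement = "moderate"
    else:  # astrocytoma: none or moderate, equally likely
        enhancement = "moderate" if rng.random() < 0.5 else "none"

    want_cavity = bool(rng.random() < spec.p_cavity)
    want_edema = bool(rng.random() < spec.p_edema)
    tumor, cavity, edema = _draw_components(
        rng, spec, centerline, cord, grid_shape, spacing, want_cavity, want_edema
    )

    tab = spec.intensity_table
    images = {}
    for contrast in ("t2w", "gd_t1w"):
        img = np.full(grid_shape, tab[(contrast, "background")], dtype=np.float32)
        img[csf] = tab[(contrast, "csf")]
        img[cord] = tab[(contrast, "cord")]
        img[edema] = tab[(contrast, "edema")]
        tumor_mean = tab[(contrast, "tumor")]
        if contrast == "gd_t1w":
            tumor_mean += ENHANCEMENT_DELTA[enhancement]
        img[tumor] = tumor_mean
        img[cavity] = tab[(contrast, "cavity")]
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=grid_shape).astype(np.float32)
        images[contrast] = ImageVolume(img, spacing)

    labels = LabelVolume.from_components(tumor, cavity, edema, spacing)
    metadata = {
        "tumor_type": tumor_type,
        "enhancement": enhancement,
        "has_edema": bool(edema.any()),
        "has_cavity": bool(cavity.any()),
        "native_spacing": spacing,
        "seed": int(subject_seed),
    }
    return SubjectRecord(
        subject_id=f"sub-{subject_seed:04d}",
        gd_t1w=images["gd_t1w"],
        t2w=images["t2w"],
        labels=labels,
        cord_mask=ImageVolume(tube.astype(np.uint8), spacing),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(
    n: int, spec: PhantomSpec, seed: int, outdir=None
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate ``n`` subjects; optionally write NIfTI files and a manifest.

    Per subject the writer emits four files (T2w, Gd-T1w, 4-channel labels,
    cord tube) plus one manifest row.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    cohort_spec = replace(spec, seed=int(seed))
    records = [generate_subject(cohort_spec, i) for i in range(n)]
    rows = []
    for rec in records:
        sp = rec.metadata["native_spacing"]
        rows.append(
            {
                "subject_id": rec.subject_id,
                "tumor_type": rec.metadata["tumor_type"],
                "has_edema": rec.metadata["has_edema"],
                "has_cavity": rec.metadata["has_cavity"],
                "spacing_si": sp[0],
                "spacing_ap": sp[1],
                "spacing_rl": sp[2],
                "seed": rec.metadata["seed"],
            }
        )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_nifti(rec.t2w, outdir / f"{rec.subject_id}_t2w.nii.gz")
            write_nifti(rec.gd_t1w, outdir / f"{rec.subject_id}_gd-t1w.nii.gz")
            write_label_volume(rec.labels, outdir / f"{rec.subject_id}_labels.nii.gz")
            write_nifti(rec.cord_mask, outdir / f"{rec.subject_id}_cordmask.nii.gz")
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return records, manifest


def load_cohort(cohort_dir) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Read a cohort previously written by :func:`generate_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    records = []
    for row in manifest.itertuples():
        sid = str(row.subject_id)
        records.append(
            SubjectRecord(
                subject_id=sid,
                gd_t1w=read_nifti(cohort_dir / f"{sid}_gd-t1w.nii.gz"),
                t2w=read_nifti(cohort_dir / f"{sid}_t2w.nii.gz"),
                labels=read_label_volume(cohort_dir / f"{sid}_labels.nii.gz"),
                cord_mask=read_nifti(cohort_dir / f"{sid}_cordmask.nii.gz"),
                metadata={
                    "tumor_type": row.tumor_type,
                    "has_edema": bool(row.has_edema),
                    "has_cavity": bool(row.has_cavity),
                    "native_spacing": (row.spacing_si, row.spacing_ap, row.spacing_rl),
                    "seed": int(row.seed),
                },
            )
        )
    return records, manifest
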