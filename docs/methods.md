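# Methods

## Problem and pipeline

Intramedullary spinal cord tumors (IMSCT) appear on MRI together with
two companion structures: liquid-filled cavities (syrinxes) and
peritumoral edema. Delineating all three, plus their union ("whole
lesion"), supports monitoring, treatment planning and surgical
decisions. The package implements a fully automatic two-stage cascade
on co-registered Gd-enhanced T1w and T2w volumes:

1. **Preprocessing.** Volumes are resampled to the standard grid of
   1 mm (superior-inferior) x 1 mm (anterior-posterior) x 2 mm
   (right-left), center cropped or zero-padded to a fixed grid
   (clinically 512 x 256 x 32 voxels = 51.2 x 25.6 x 6.4 cm), and
   z-scored (subtract mean, divide by standard deviation). Every
   spatial operation is logged in an invertible transform record.
2. **Cord localization.** A modified 3D U-Net (depth 4, 8 base
   filters, single T2w channel, batch 1, one full-grid patch) predicts
   the cord region; ground truth during training is a 30 mm-diameter
   tube around the cord centerline. The predicted mask, binarized at
   0.5, is converted to a 3D bounding box with a 5 mm margin per axis.
3. **Tumor segmentation.** Both contrasts are cropped to the box,
   re-normalized, and fed as a 2-channel input to a second U-Net
   (depth 4, 16 base filters, 4 sigmoid output channels: tumor,
   cavity, edema, whole). Inference runs on a 128 x 128 x 32 patch
   grid with 64 x 64 x 32 stride; overlapping predictions are stitched
   by voxelwise averaging.
4. **Postprocessing.** Per channel: binarize at 0.5 (ties to
   foreground), fill holes (6-connected background), remove
   26-connected components with physical volume strictly below
   0.2 cm^3 (tumor, whole) or 0.5 cm^3 (cavity, edema). The whole
   channel is *not* reconciled with the union of the structure
   channels; the mismatch is logged.
5. **Native-space restoration.** The binary prediction is embedded
   back into the standard grid and resampled (nearest) onto the
   original scan grid via the recorded transform.

Sigmoid outputs (not softmax) keep the four channels independent so a
union class can be trained jointly with its parts.

## Network and training

The U-Net follows the BraTS-2017-style modification of the original
3D U-Net: instance normalization (stable at batch size 1), leaky ReLU
(slope 0.01), dropout, trilinear upsampling + convolution in the
decoder, and deep supervision in the summed-logits form — 1x1x1
segmentation heads at the two coarsest decoder levels whose outputs
are upsampled and added into the final logits before the sigmoid.
Filter count doubles per level; two conv-norm-act blocks per level.

Both stages train with the (multiclass) Dice loss

    L = 1 - (2 * sum(p*g) + s) / (sum(p) + sum(g) + s),

averaged over the four channels for the segmenter (the whole-lesion
channel counts like any other), with smoothing s = 1 by default.
Optimization is Adam (default moments) at initial learning rate 0.001
under a single cosine-annealing cycle spanning the epoch budget, and
early stopping with patience 50 and epsilon 0.001 (an improvement must
exceed the epsilon strictly). Validation loss is the multiclass Dice
loss of stitched full-volume inference on the validation subjects —
the quantity early stopping should actually protect. Augmentation per
sample: rotation uniform in +/-5 degrees about one random axis,
isotropic scaling +/-10% in the sagittal plane, translation +/-3% of
the sagittal extents; the identical transform is applied to both
contrasts and all label channels (labels nearest-interpolated and
re-binarized). Subjects split 60/20/20 by subject; floored fractions
with remainders assigned to training.

Because no deep-learning framework is part of the dependency set, the
network is an explicit numpy computation graph with hand-derived
backpropagation. Convolutions run in a channels-last internal layout:
3x3x3 layers with few input channels go through a compiled (numba)
direct kernel, wider layers through a per-tap BLAS formulation; both
are exact and deterministic. All analytic gradients are validated
against central finite differences in the test suite.

## Synthetic phantom cohorts

No public IMSCT dataset exists, so the phantom module generates
statistically matched cohorts:

* **Geometry.** A sinusoidally curved cord centerline spans the full
  S-I extent; the cord is a 13 mm-diameter tube (the adult average)
  with a CSF sheath, plus the 30 mm localization tube. Lesion
  components are ellipsoids deformed along the centerline (circular
  cross-sections centered on the cord axis), chosen for analytic
  volume control. Lesion lengths are log-normal (medians 12 / 14 /
  10 mm for tumor / cavity / edema) — scaled-down counterparts of the
  clinical volume heterogeneity, not a fit to it. Edema, when
  present, is seeded at a tumor pole and carved back so it always
  touches the tumor; the cavity sits along the cord with a random gap
  and may be disjoint from the tumor. All pathology is intersected
  with the cord (intramedullary by construction).
* **Resolution.** Subjects get native grids from per-subject spacing
  draws: in-plane uniform in [0.34, 1.33] mm, slice thickness in
  [1.5, 5.2] mm, against a fixed physical extent. The pipeline's
  resampler is therefore genuinely exercised.
* **Intensities.** Noise-free tissue means follow the qualitative
  radiology: on T2w, cavity > edema > tumor >= cord > background with
  bright CSF; on Gd-T1w, CSF and cavity are dark (cavities never
  enhance) and tumor enhancement depends on type — hemangioblastoma
  strong, ependymoma moderate, astrocytoma none or moderate with
  equal probability (the literature gives no proportions). Additive
  Gaussian noise (sd 10, i.e. 20% of the smallest inter-tissue gap)
  is the simplest model that exercises normalization.
* **Cohort composition.** 67% of subjects carry a cavity, 51% edema;
  tumor types are drawn 101 : 122 : 120
  (astrocytoma : ependymoma : hemangioblastoma). One tumor blob by
  default; a multi-blob option exists.

What the phantoms do **not** model: vertebrae and other extradural
anatomy, motion/flow artifacts, bias fields, partial-volume effects,
ill-defined infiltrative boundaries, and inter-rater ambiguity. Tissue
classes are homogeneous apart from additive noise, so phantom
segmentation is much easier than clinical segmentation: passing the
desk-scale study shows the pipeline is implemented coherently and can
recover a known generative model end to end — it says nothing about
clinical-grade accuracy.

## Evaluation

Per structure and subject: Dice (a false positive for a structure the
subject does not have scores 0; empty-empty cases are excluded from
averages, with exclusion counts reported); detection at >= 6 mm^3
physical overlap (inclusive), with the same volume floor defining a
false-positive detection for absent structures; voxel precision and
recall (precision undefined for empty predictions); relative volume
difference (V_gt - V_pred)/V_gt, negative = over-segmentation, and its
absolute value. Cohort means are computed per split and aggregated as
mean +/- population standard deviation across repeated random splits.
Localization is scored by the Dice of the predicted cord mask against
the 30 mm tube plus the fraction of subjects whose whole-lesion ground
truth is fully inside the recorded bounding box (half-open voxel
boxes). Metrics are computed in standard space, before native-space
inversion.

## Desk-scale study sizes

The end-to-end study in `imsctseg.experiment` (what
`scripts/acceptance.py` reports) uses 40 phantoms on a 96 x 48 x 24
standard grid at (1, 1, 2) mm, a depth-3 localizer with 4 base filters
trained for up to 8 epochs, and a depth-3 segmenter with 8 base
filters, 32 x 32 x 16 patches, 16 x 16 x 16 stride and batch 8 for up
to 6 epochs (patience 4, dropout 0.1). These budgets sit where the
stages converge on phantoms; the cosine schedule spans the budget.
Training uses the ground-truth cord tube to derive the segmenter's
crops (the training-time analogue of the manual cord masks), while
held-out evaluation runs the full cascade including the learned
localizer.

## Numerical choices

* Voxel indices are 0-based; boxes are half-open `[lo, hi)`.
* Odd crop/pad differences put the extra voxel on the high-index side.
* Resampled grid sizes are `round(extent / target_spacing)` with
  round-half-to-even; voxel centers are corner-aligned.
* Linear interpolation for images, nearest for masks.
* Constant-intensity volumes raise an error rather than produce NaNs.
* Binarization ties (exactly 0.5) go to foreground; the volume floor
  removes components *strictly* below it.
* Max-pool gradient splits equally among tied maxima; instance-norm
  epsilon is 1e-5; Dice-loss smoothing defaults to 1.
* Splits use floored fractions, remainders to train; std across splits
  is the population (n) form.
* All randomness flows through named integer seeds (cohort, split,
  initialization, dropout, augmentation), so identical seeds give
  bitwise-identical manifests, splits and training logs.

## Known limitations

* The phantom's simplicity means phantom metrics overestimate clinical
  performance by a wide margin; clinical numbers require clinical data.
* T1w-T2w registration is out of scope: inputs are assumed (and
  phantoms are generated) co-registered.
* The cascaded-vs-single-step comparison is provided as a harness
  (`run_single_step`, `--no-cascade`); the direction of the effect is
  not asserted by tests.
* Training is CPU-bound and sized for desk-scale experiments; clinical
  grids (512 x 256 x 32, depth 4, 200 epochs) are expressible in the
  same configs but not practical without acceleration.
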