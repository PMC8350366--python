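"""Losses, augmentation, patch sampling, schedules and the training loop.

Both cascade stages share one loop: the cord localizer trains on a single
full-grid T2w patch with batch size 1, the tumor segmenter on a stride
grid of two-contrast patches with batch size 8.  The loss is the
(multiclass) Dice loss — one minus the smoothed overlap ratio, averaged
over channels — optimized with Adam under one cosine-annealing cycle and
early stopping on the stitched-inference validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .net3d import UNet3D, UNetConfig, build_unet

# ---------------------------------------------------------------------------
# Dice losses


def _dice_terms(pred, target, smooth):
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum()) + smooth
    return (2.0 * inter + smooth), denom


def dice_loss(pred_soft, target_binary, smooth: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2 sum(p g) + s) / (sum p + sum g + s)``."""
    pred_soft = np.asarray(pred_soft, dtype=np.float64)
    target_binary = np.asarray(target_binary, dtype=np.float64)
    if pred_soft.shape != target_binary.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_soft.shape} vs target {target_binary.shape}"
        )
    num, den = _dice_terms(pred_soft, target_binary, smooth)
    return 1.0 - num / den


def multiclass_dice_loss(pred_soft, target, smooth: float = 1.0) -> float:
    """Unweighted mean of per-channel Dice losses (channel axis 0).

    The whole-lesion channel participates like any other channel.
    """
    pred_soft = np.asarray(pred_soft)
    target = np.asarray(target)
    if pred_soft.shape != target.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_soft.shape} vs target {target.shape}"
        )
    return float(
        np.mean([dice_loss(p, g, smooth) for p, g in zip(pred_soft, target)])
    )


def batch_dice_loss_and_grad(pred, target, smooth: float = 1.0):
    """Mean per-(sample, channel) Dice loss and its gradient wrt ``pred``.

    ``pred`` and ``target`` are ``(N, C, X, Y, Z)``; the loss averages the
    per-sample per-channel Dice losses, matching the training objective.
    """
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    axes = (2, 3, 4)
    inter = (pred * target).sum(axis=axes)
    num = 2.0 * inter + smooth
    den = pred.sum(axis=axes) + target.sum(axis=axes) + smooth
    loss = float(np.mean(1.0 - num / den))
    nc = pred.shape[0] * pred.shape[1]
    num_b = num[:, :, None, None, None]
    den_b = den[:, :, None, None, None]
    grad = -(2.0 * target * den_b - num_b) / (den_b**2) / nc
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# Patch sampling


def patch_origins_1d(length: int, patch: int, stride: int) -> list[int]:
    """Stride-grid origins along one axis, with the last origin clamped so
    the final patch ends exactly at the border (no voxel missed)."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    if patch > length:
        raise ValueError(f"patch {patch} exceeds axis length {length}")
    origins = list(range(0, length - patch + 1, stride))
    if origins[-1] != length - patch:
        origins.append(length - patch)
    return origins


def extract_patches(vol: np.ndarray, patch_size, stride):
    """Split a ``(..., X, Y, Z)`` array into an ordered patch grid.

    Returns a list of ``(patch, origin)`` where ``origin`` is the 3-tuple
    voxel offset of the patch in the volume.  Every voxel is covered by at
    least one patch.
    """
    vol = np.asarray(vol)
    shape = vol.shape[-3:]
    axes_origins = [
        patch_origins_1d(n, p, s) for n, p, s in zip(shape, patch_size, stride)
    ]
    out = []
    for o0 in axes_origins[0]:
        for o1 in axes_origins[1]:
            for o2 in axes_origins[2]:
                sl = (
                    ...,
                    slice(o0, o0 + patch_size[0]),
                    slice(o1, o1 + patch_size[1]),
                    slice(o2, o2 + patch_size[2]),
                )
                out.append((vol[sl], (o0, o1, o2)))
    return out


def pad_to_shape(vol: np.ndarray, min_shape) -> tuple[np.ndarray, tuple]:
    """Zero-pad trailing spatial axes up to ``min_shape`` (pad on the
    high-index side); returns the padded array and the original shape."""
    shape = vol.shape[-3:]
    pads = [(0, max(0, m - n)) for n, m in zip(shape, min_shape)]
    full = [(0, 0)] * (vol.ndim - 3) + pads
    return np.pad(vol, full), shape


# ---------------------------------------------------------------------------
# Augmentation


@dataclass
class TrainConfig:
    """Training hyperparameters for one cascade stage."""

    lr: float = 0.001
    lr_min: float = 0.0
    max_epochs: int = 200
    patience: int = 50
    min_delta: float = 0.001
    batch_size: int = 1
    patch_size: tuple[int, int, int] = (512, 256, 32)
    stride: tuple[int, int, int] | None = None  # None -> patch_size (one grid cell)
    augment: bool = True
    aug_rotate_deg: float = 5.0
    aug_scale: float = 0.10
    aug_translate: float = 0.03
    random_patch_offset: bool = False
    loss_smooth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.stride is None:
            self.stride = tuple(self.patch_size)
        if any(s > p for s, p in zip(self.stride, self.patch_size)):
            raise ValueError("stride must not exceed patch size per axis")


def _affine_params(cfg: TrainConfig, rng):
    axis = int(rng.integers(0, 3))
    angle = float(rng.uniform(-cfg.aug_rotate_deg, cfg.aug_rotate_deg))
    scale = float(rng.uniform(1.0 - cfg.aug_scale, 1.0 + cfg.aug_scale))
    shift = [
        float(rng.uniform(-cfg.aug_translate, cfg.aug_translate)),
        float(rng.uniform(-cfg.aug_translate, cfg.aug_translate)),
    ]
    return axis, angle, scale, shift


def affine_matrix(axis: int, angle_deg: float, scale: float, shift_frac, shape):
    """Forward affine map of the augmentation draw.

    Rotation of ``angle_deg`` about one voxel axis, isotropic scaling in
    the sagittal (S-I x A-P) plane, and translation as a fraction of the
    sagittal extents; all about the volume center.  Returns ``(A, t)``
    such that an object point ``x`` moves to ``A @ (x - c) + c + t``.
    """
    th = np.deg2rad(angle_deg)
    R = np.eye(3)
    i, j = [a for a in range(3) if a != axis]
    R[i, i] = R[j, j] = np.cos(th)
    R[i, j] = -np.sin(th)
    R[j, i] = np.sin(th)
    S = np.diag([scale, scale, 1.0])  # sagittal-plane scaling
    t = np.array([shift_frac[0] * shape[0], shift_frac[1] * shape[1], 0.0])
    return R @ S, t


def augment(images: np.ndarray, labels: np.ndarray, cfg: TrainConfig, rng):
    """Apply one random affine draw identically to all image and label
    channels (images linear, labels nearest + re-binarized)."""
    axis, angle, scale, shift = _affine_params(cfg, rng)
    if angle == 0.0 and scale == 1.0 and shift == [0.0, 0.0]:
        return images.copy(), labels.copy()
    shape = images.shape[-3:]
    A, t = affine_matrix(axis, angle, scale, shift, shape)
    Ainv = np.linalg.inv(A)
    c = (np.asarray(shape) - 1) / 2.0
    offset = c - Ainv @ (c + t)
    out_imgs = np.stack(
        [
            ndimage.affine_transform(ch, Ainv, offset=offset, order=1, mode="nearest")
            for ch in images
        ]
    ).astype(np.float32)
    out_lbls = np.stack(
        [
            ndimage.affine_transform(
                ch.astype(np.float32), Ainv, offset=offset, order=0, mode="constant"
            )
            for ch in labels
        ]
    )
    return out_imgs, (out_lbls > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Schedules and stopping


def cosine_lr(epoch: int, max_epochs: int, lr0: float, lr_min: float = 0.0) -> float:
    """One cosine-annealing cycle from ``lr0`` down to ``lr_min``."""
    if not 0 <= epoch <= max_epochs:
        raise ValueError("epoch outside [0, max_epochs]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * epoch / max_epochs))


def early_stop_check(val_loss_history, patience: int, min_delta: float) -> bool:
    """True iff none of the last ``patience`` epochs improved the best
    validation loss by strictly more than ``min_delta``.

    The running best tracks the minimum seen so far unconditionally, so a
    sequence of epsilon-sized improvements (each exactly ``min_delta``)
    never counts as progress and triggers the stop after ``patience``
    epochs.
    """
    history = list(val_loss_history)
    if not history:
        raise ValueError("history must be non-empty")
    best = history[0]
    last_improvement = 0
    for t in range(1, len(history)):
        if history[t] < best - min_delta:
            last_improvement = t
        best = min(best, history[t])
    return (len(history) - 1 - last_improvement) >= patience


# ---------------------------------------------------------------------------
# Dataset splitting


@dataclass
class SplitPlan:
    """Subject-level split into train / validation / test."""

    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float]
    seed: int

    def assignment(self) -> dict[str, str]:
        out = {}
        for name in ("train", "validation", "test"):
            for sid in getattr(self, name):
                out[sid] = name
        return out


def split_dataset(manifest, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> SplitPlan:
    """Reproducible subject-level split.

    Fraction rounding: each fraction is floored to a subject count and all
    remainders go to the training set.
    """
    if isinstance(manifest, pd.DataFrame):
        ids = [str(s) for s in manifest["subject_id"]]
    else:
        ids = [str(s) for s in manifest]
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return SplitPlan(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        fractions=tuple(fractions),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam with default moments; learning rate supplied per step."""

    def __init__(self, model: UNet3D, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]

    def step(self, lr: float) -> None:
        self.t += 1
        for (p, g), m, v in zip(self.model.params(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class Sample:
    """One preprocessed training example (standard-space arrays)."""

    subject_id: str
    image: np.ndarray  # (C_in, X, Y, Z) float32, z-scored
    target: np.ndarray  # (C_out, X, Y, Z) uint8


@dataclass
class TrainedModel:
    model: UNet3D
    log: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    stopped_epoch: int


def get_state(model: UNet3D) -> list[np.ndarray]:
    return [p.copy() for p, _ in model.params()]


def set_state(model: UNet3D, state) -> None:
    for (p, _), s in zip(model.params(), state):
        p[...] = s


def save_checkpoint(model: UNet3D, path) -> None:
    """Serialize weights together with the architecture config."""
    import json
    from dataclasses import asdict

    meta = json.dumps(asdict(model.cfg))
    arrays = {f"p{i:04d}": p for i, (p, _) in enumerate(model.params())}
    np.savez_compressed(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> UNet3D:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = build_unet(UNetConfig(**meta))
        keys = sorted(k for k in data.files if k != "_meta")
        set_state(model, [data[k] for k in keys])
    return model


def _sample_patches(sample: Sample, cfg: TrainConfig, rng):
    img, tgt = sample.image, sample.target
    if cfg.augment:
        img, tgt = augment(img, tgt, cfg, rng)
    img, _ = pad_to_shape(img, cfg.patch_size)
    tgt, _ = pad_to_shape(tgt, cfg.patch_size)
    if cfg.random_patch_offset:
        shape = img.shape[-3:]
        origin = tuple(
            int(rng.integers(0, n - p + 1)) for n, p in zip(shape, cfg.patch_size)
        )
        sl = (...,) + tuple(slice(o, o + p) for o, p in zip(origin, cfg.patch_size))
        return [(img[sl], tgt[sl])]
    img_patches = extract_patches(img, cfg.patch_size, cfg.stride)
    tgt_patches = extract_patches(tgt, cfg.patch_size, cfg.stride)
    return [(ip, tp) for (ip, _), (tp, _) in zip(img_patches, tgt_patches)]


def _validation_loss(model, val_samples, cfg: TrainConfig) -> float:
    from .cascade import sliding_window_predict  # local import: cascade uses us too

    losses = []
    for sample in val_samples:
        pred = sliding_window_predict(model, sample.image, cfg.patch_size, cfg.stride)
        losses.append(multiclass_dice_loss(pred, sample.target, cfg.loss_smooth))
    return float(np.mean(losses))


def train_model(
    train_samples: list[Sample],
    val_samples: list[Sample],
    net_cfg: UNetConfig,
    cfg: TrainConfig,
) -> TrainedModel:
    """Train one cascade stage; fully reproducible given the seeds.

    Returns the weights of the epoch with the lowest stitched-inference
    validation loss, together with the per-epoch log.
    """
    if not train_samples:
        raise ValueError("empty training set")
    model = build_unet(net_cfg, seed=cfg.seed)
    rng = np.random.default_rng([cfg.seed, 1])
    model.set_dropout_rng(np.random.default_rng([cfg.seed, 2]))
    optimizer = Adam(model)

    log_rows = []
    val_history: list[float] = []
    best_state = get_state(model)
    best_epoch, best_val = -1, np.inf
    stopped = cfg.max_epochs
    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(epoch, cfg.max_epochs, cfg.lr, cfg.lr_min)
        pairs = []
        for idx in rng.permutation(len(train_samples)):
            pairs.extend(_sample_patches(train_samples[idx], cfg, rng))
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            x = np.stack([pairs[i][0] for i in batch_idx]).astype(np.float32)
            y = np.stack([pairs[i][1] for i in batch_idx]).astype(np.float32)
            pred = model.forward(x, training=True)
            loss, grad = batch_dice_loss_and_grad(pred, y, cfg.loss_smooth)
            model.zero_grad()
            model.backward(grad)
            optimizer.step(lr)
            epoch_losses.append(loss)
        val_loss = _validation_loss(model, val_samples, cfg) if val_samples else float(
            np.mean(epoch_losses)
        )
        val_history.append(val_loss)
        log_rows.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = get_state(model)
        if early_stop_check(val_history, cfg.patience, cfg.min_delta):
            stopped = epoch + 1
            break
    set_state(model, best_state)
    return TrainedModel(
        model=model,
        log=pd.DataFrame(log_rows),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        stopped_epoch=stopped,
    )
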