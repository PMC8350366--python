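"""Losses, patch grids, schedules, stopping, splitting, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imsctseg.net3d import UNetConfig
from imsctseg.train import (
    Sample,
    TrainConfig,
    augment,
    batch_dice_loss_and_grad,
    cosine_lr,
    dice_loss,
    early_stop_check,
    extract_patches,
    multiclass_dice_loss,
    patch_origins_1d,
    split_dataset,
    train_model,
)


class TestDiceLoss:
    def test_perfect_prediction(self, rng):
        g = (rng.random((6, 6, 6)) > 0.5).astype(float)
        assert dice_loss(g, g, smooth=1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_disjoint_prediction(self):
        p = np.zeros((4, 4, 4))
        g = np.zeros((4, 4, 4))
        p[0], g[1] = 1, 1
        assert dice_loss(p, g, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_half_constant_hand_computation(self):
        # pred 0.5 everywhere, target ones on half of a 2x2x2 grid:
        # inter = 0.5*4 = 2, sums = 4 + 4; loss = 1 - (2*2+s)/(8+s)
        p = np.full((2, 2, 2), 0.5)
        g = np.zeros((2, 2, 2))
        g[:, :, 0] = 1
        s = 1.0
        expected = 1 - (2 * 2 + s) / (8 + s)
        assert dice_loss(p, g, smooth=s) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestMulticlassDiceLoss:
    def test_all_channels_perfect(self, rng):
        g = (rng.random((4, 5, 5, 5)) > 0.5).astype(float)
        assert multiclass_dice_loss(g, g, smooth=1e-9) == pytest.approx(0.0, abs=1e-7)

    def test_two_perfect_two_wrong(self):
        g = np.zeros((4, 3, 3, 3))
        g[:, 0] = 1
        p = g.copy()
        p[2:] = 1 - g[2:]  # two channels complemented
        assert multiclass_dice_loss(p, g, smooth=1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_equals_per_channel_mean_oracle(self, rng):
        p = rng.random((4, 6, 6, 4))
        g = (rng.random((4, 6, 6, 4)) > 0.6).astype(float)
        oracle = np.mean([dice_loss(p[c], g[c], 1.0) for c in range(4)])
        assert multiclass_dice_loss(p, g, 1.0) == pytest.approx(oracle, rel=1e-12)

    def test_channel_mismatch(self):
        with pytest.raises(ValueError):
            multiclass_dice_loss(np.zeros((4, 2, 2, 2)), np.zeros((3, 2, 2, 2)))


def test_batch_loss_gradient_matches_finite_differences(rng):
    p = rng.random((2, 3, 4, 4, 2)).astype(np.float64)
    g = (rng.random((2, 3, 4, 4, 2)) > 0.5).astype(np.float64)
    loss, grad = batch_dice_loss_and_grad(p, g, smooth=1.0)
    picker = np.random.default_rng(0)
    flat = p.reshape(-1)
    for idx in picker.choice(flat.size, 8, replace=False):
        # epsilon large enough to survive the float32 loss accumulation
        eps = 1e-3
        orig = flat[idx]
        flat[idx] = orig + eps
        lp, _ = batch_dice_loss_and_grad(p, g, smooth=1.0)
        flat[idx] = orig - eps
        lm, _ = batch_dice_loss_and_grad(p, g, smooth=1.0)
        flat[idx] = orig
        assert grad.reshape(-1)[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-2, abs=1e-6)


class TestPatchGrid:
    @pytest.mark.parametrize(
        "length,patch,stride,expected",
        [
            (128, 128, 64, [0]),
            (192, 128, 64, [0, 64]),
            (200, 128, 64, [0, 64, 72]),  # last origin clamped to the border
            (32, 32, 32, [0]),
        ],
    )
    def test_origins(self, length, patch, stride, expected):
        assert patch_origins_1d(length, patch, stride) == expected

    def test_zero_stride_rejected(self):
        with pytest.raises(ValueError):
            patch_origins_1d(64, 32, 0)

    def test_single_patch_volume(self, rng):
        vol = rng.normal(size=(128, 128, 32))
        patches = extract_patches(vol, (128, 128, 32), (64, 64, 32))
        assert len(patches) == 1 and patches[0][1] == (0, 0, 0)

    @settings(max_examples=25, deadline=None)
    @given(
        shape=st.tuples(*[st.integers(8, 40)] * 3),
        patch=st.tuples(*[st.integers(4, 8)] * 3),
        stride=st.tuples(*[st.integers(1, 8)] * 3),
    )
    def test_every_voxel_covered(self, shape, patch, stride):
        stride = tuple(min(s, p) for s, p in zip(stride, patch))
        covered = np.zeros(shape, dtype=int)
        for _, origin in extract_patches(np.zeros(shape), patch, stride):
            sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
            covered[sl] += 1
        assert (covered >= 1).all()


class TestAugment:
    def _cfg(self, **kw):
        base = dict(aug_rotate_deg=0.0, aug_scale=0.0, aug_translate=0.0,
                    patch_size=(8, 8, 8), stride=(8, 8, 8))
        base.update(kw)
        return TrainConfig(max_epochs=10, patience=5, **base)

    def test_zero_amplitudes_identity(self, rng):
        img = rng.normal(size=(2, 10, 10, 6)).astype(np.float32)
        lbl = (rng.random((4, 10, 10, 6)) > 0.5).astype(np.uint8)
        out_img, out_lbl = augment(img, lbl, self._cfg(), np.random.default_rng(0))
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_lbl, lbl)

    def test_labels_stay_binary(self, rng):
        img = rng.normal(size=(1, 16, 16, 8)).astype(np.float32)
        lbl = (rng.random((4, 16, 16, 8)) > 0.5).astype(np.uint8)
        cfg = self._cfg(aug_rotate_deg=5, aug_scale=0.1, aug_translate=0.03)
        for seed in range(5):
            _, out = augment(img, lbl, cfg, np.random.default_rng(seed))
            assert set(np.unique(out)).issubset({0, 1})

    def test_marked_voxel_moves_to_analytic_position(self):
        from imsctseg.train import _affine_params, affine_matrix

        cfg = self._cfg(aug_rotate_deg=5, aug_scale=0.1, aug_translate=0.03)
        shape = (24, 24, 12)
        lbl = np.zeros((1,) + shape, dtype=np.uint8)
        pos = np.array([15, 9, 6])
        lbl[0][tuple(pos)] = 1
        img = np.zeros((1,) + shape, dtype=np.float32)
        # replay the parameter draw with an identically seeded generator
        axis, angle, scale, shift = _affine_params(cfg, np.random.default_rng(3))
        A, t = affine_matrix(axis, angle, scale, shift, shape)
        c = (np.asarray(shape) - 1) / 2
        expected = A @ (pos - c) + c + t
        _, out = augment(img, lbl, cfg, np.random.default_rng(3))
        moved = np.argwhere(out[0] > 0)
        assert len(moved) >= 1
        dist = np.abs(moved - expected).max(axis=1).min()
        assert dist <= 1.0  # nearest-neighbour rounding slack


class TestSchedules:
    def test_cosine_endpoints_and_midpoint(self):
        assert cosine_lr(0, 200, 0.001) == pytest.approx(0.001)
        assert cosine_lr(200, 200, 0.001) == pytest.approx(0.0)
        assert cosine_lr(100, 200, 0.001) == pytest.approx(0.0005)

    def test_cosine_monotone_nonincreasing(self):
        lrs = [cosine_lr(e, 50, 0.001) for e in range(51)]
        assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))

    def test_early_stop_never_on_steady_improvement(self):
        history = [1.0 - 0.01 * i for i in range(60)]
        assert not early_stop_check(history, patience=50, min_delta=0.001)

    def test_early_stop_on_flat_history(self):
        assert early_stop_check([0.5] * 6, patience=5, min_delta=0.001)

    def test_improvement_of_exactly_min_delta_does_not_count(self):
        # strict inequality: epsilon-sized steps are not improvements
        history = [1.0 - 0.001 * i for i in range(10)]
        assert early_stop_check(history, patience=5, min_delta=0.001)


class TestSplit:
    def test_fraction_rounding(self):
        plan = split_dataset([f"s{i}" for i in range(10)], (0.6, 0.2, 0.2), seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (6, 2, 2)

    def test_reproducible(self):
        ids = [f"s{i}" for i in range(17)]
        a = split_dataset(ids, seed=4)
        b = split_dataset(ids, seed=4)
        assert a == b

    def test_disjoint_exhaustive_many_seeds(self):
        ids = [f"s{i}" for i in range(11)]
        for seed in range(100):
            plan = split_dataset(ids, seed=seed)
            parts = plan.train + plan.validation + plan.test
            assert sorted(parts) == sorted(ids)
            assert len(set(parts)) == len(ids)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            split_dataset(["a", "b"], seed=0)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            split_dataset([f"s{i}" for i in range(5)], (0.5, 0.2, 0.2), seed=0)


def _toy_samples(subject, n=6):
    """Tiny localizer-style samples from shifted crops of one phantom."""
    t2 = subject.t2w.data.astype(np.float32)
    t2 = (t2 - t2.mean()) / t2.std()
    tube = subject.cord_mask.data
    samples = []
    for i in range(n):
        sl = (slice(i, i + 32), slice(0, 16), slice(0, 8))
        samples.append(Sample(f"s{i}", t2[sl][None], tube[sl][None].astype(np.uint8)))
    return samples


class TestTrainModel:
    def test_training_loss_trends_down(self, subject):
        samples = _toy_samples(subject)
        cfg = TrainConfig(max_epochs=5, patience=5, batch_size=2,
                          patch_size=(32, 16, 8), augment=False, seed=0)
        net = UNetConfig(1, 1, depth=2, base_filters=2, dropout_rate=0.0)
        trained = train_model(samples[:4], samples[4:], net, cfg)
        rho = stats.spearmanr(trained.log["epoch"], trained.log["train_loss"]).statistic
        assert rho < 0

    def test_forced_early_stop(self, subject):
        samples = _toy_samples(subject)
        cfg = TrainConfig(max_epochs=10, patience=1, min_delta=1e9, batch_size=2,
                          patch_size=(32, 16, 8), augment=False, seed=0)
        net = UNetConfig(1, 1, depth=2, base_filters=2, dropout_rate=0.0)
        trained = train_model(samples[:4], samples[4:], net, cfg)
        assert trained.stopped_epoch == 2

    def test_best_weights_reproduce_logged_val_loss(self, subject):
        from imsctseg.train import _validation_loss

        samples = _toy_samples(subject)
        cfg = TrainConfig(max_epochs=3, patience=3, batch_size=2,
                          patch_size=(32, 16, 8), augment=False, seed=0)
        net = UNetConfig(1, 1, depth=2, base_filters=2, dropout_rate=0.0)
        trained = train_model(samples[:4], samples[4:], net, cfg)
        re_eval = _validation_loss(trained.model, samples[4:], cfg)
        assert re_eval == pytest.approx(trained.best_val_loss, rel=1e-5)

    def test_empty_training_set(self, subject):
        cfg = TrainConfig(max_epochs=2, patience=2, patch_size=(32, 16, 8))
        with pytest.raises(ValueError):
            train_model([], _toy_samples(subject)[:1],
                        UNetConfig(1, 1, depth=2, base_filters=2), cfg)

    def test_checkpoint_roundtrip(self, subject, tmp_path):
        from imsctseg.train import load_checkpoint, save_checkpoint

        samples = _toy_samples(subject)
        cfg = TrainConfig(max_epochs=1, patience=1, batch_size=2,
                          patch_size=(32, 16, 8), augment=False, seed=0)
        net = UNetConfig(1, 1, depth=2, base_filters=2, dropout_rate=0.0)
        trained = train_model(samples[:4], samples[4:], net, cfg)
        save_checkpoint(trained.model, tmp_path / "w.npz")
        loaded = load_checkpoint(tmp_path / "w.npz")
        x = samples[0].image[None]
        np.testing.assert_array_equal(loaded.forward(x), trained.model.forward(x))
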