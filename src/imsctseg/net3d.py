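"""Modified 3D U-Net as an explicit numpy computation graph.

The architecture is an encoder-decoder with two convolution blocks per
resolution level, instance normalization, leaky ReLU, dropout, trilinear
upsampling in the decoder, and deep supervision: 1x1x1 segmentation heads
at the two coarsest decoder levels whose upsampled logits are summed into
the final logits before a sigmoid.  Sigmoid (not softmax) output keeps
the channels independent, which is what allows a "whole lesion" channel
composed of all structures to coexist with the per-structure channels.

Forward and backward passes are written by hand on float32 arrays; every
layer implements the adjoint of its forward map, and analytic gradients
are verified against central finite differences in the test suite.
Convolutions run through compiled direct kernels (``_kernels``) in a
channels-last internal layout so the hot loops vectorize over channels;
a pure-numpy path is used when numba is unavailable.

The public interface is channels-first: ``forward`` maps
``(N, C_in, X, Y, Z)`` to ``(N, C_out, X, Y, Z)`` with the spatial axes
in the package-wide (S-I, A-P, R-L) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # compiled direct-conv kernel for few-channel inputs
    from ._kernels import conv3_forward

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts downsampling levels; input spatial dimensions must be
    divisible by ``2**depth``.  The clinical models use depth 4 with 8
    base filters (cord localizer, 1 input / 1 output channel) and 16 base
    filters (tumor segmenter, 2 inputs / 4 outputs).
    """

    in_channels: int = 1
    out_channels: int = 1
    depth: int = 4
    base_filters: int = 8
    dropout_rate: float = 0.3
    leaky_slope: float = 0.01
    deep_supervision: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Layers (internal layout: channels-last, (N, X, Y, Z, C))


class Conv3d:
    """3D convolution, stride 1, 'same' zero padding (kernel 3) or 1x1x1."""

    def __init__(self, cin, cout, ksize, rng):
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize**3
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (ksize, ksize, ksize, cin, cout)
        ).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @staticmethod
    def _corr(x, W, b):
        """Stride-1 'same' correlation; x is (N, X, Y, Z, Cin).

        Few-channel inputs go through the compiled direct kernel; wider
        layers run a tap loop of per-offset BLAS channel mixes, whose
        shifted accumulations are contiguous in the channels-last layout.
        """
        n, X, Y, Z, cin = x.shape
        k, cout = W.shape[0], W.shape[4]
        if k == 1:
            return x @ W[0, 0, 0] + b
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        if _HAVE_NUMBA and cin <= 2:
            out = np.empty((n, X, Y, Z, cout), dtype=np.float32)
            conv3_forward(xp, W, b, out)
            return out
        out = np.empty((n, X, Y, Z, cout), dtype=np.float32)
        out[...] = b
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    t = xp @ W[dx, dy, dz]
                    out += t[:, dx : dx + X, dy : dy + Y, dz : dz + Z, :]
        return out

    def forward(self, x, training=False):
        self._x = x
        return self._corr(x, self.W, self.b)

    def backward(self, g):
        x = self._x
        n, X, Y, Z, _ = x.shape
        k = self.k
        g = np.ascontiguousarray(g, dtype=np.float32)
        if k == 1:
            x2 = x.reshape(-1, self.cin)
            g2 = g.reshape(-1, self.cout)
            self.gW[0, 0, 0] += x2.T @ g2
            self.gb += g2.sum(axis=0)
            return (g2 @ self.W[0, 0, 0].T).reshape(x.shape)
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        g2 = g.reshape(-1, self.cout)
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, dx : dx + X, dy : dy + Y, dz : dz + Z, :]
                    ).reshape(-1, self.cin)
                    self.gW[dx, dy, dz] += xs.T @ g2
        self.gb += g.sum(axis=(0, 1, 2, 3))
        # gradient wrt input: correlate g with the spatially flipped,
        # channel-transposed kernel (exact for stride-1 same convolution)
        Wf = np.ascontiguousarray(self.W[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3))
        return self._corr(g, Wf, np.zeros(self.cin, dtype=np.float32))

    def params(self):
        yield self.W, self.gW
        yield self.b, self.gb

    def n_params(self):
        return self.W.size + self.b.size


class InstanceNorm3d:
    """Per-sample per-channel normalization with learnable affine."""

    eps = 1e-5

    def __init__(self, channels):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x, training=False):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        xhat, istd = self._xhat, self._istd
        m = float(np.prod(g.shape[1:4]))
        gxhat = g * self.gamma
        self.ggamma += (g * xhat).sum(axis=(0, 1, 2, 3))
        self.gbeta += g.sum(axis=(0, 1, 2, 3))
        s1 = gxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (istd / m) * (m * gxhat - s1 - xhat * s2)

    def params(self):
        yield self.gamma, self.ggamma
        yield self.beta, self.gbeta

    def n_params(self):
        return self.gamma.size + self.beta.size


class LeakyReLU:
    def __init__(self, slope):
        self.slope = slope

    def forward(self, x, training=False):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, g):
        return np.where(self._neg, self.slope * g, g)

    def params(self):
        return iter(())

    def n_params(self):
        return 0


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate):
        self.rate = rate
        self.rng = np.random.default_rng(0)  # replaced via set_dropout_rng
        self._mask = None

    def forward(self, x, training=False):
        if training and self.rate > 0.0:
            keep = 1.0 - self.rate
            self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
            return x * self._mask
        self._mask = None
        return x

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return iter(())

    def n_params(self):
        return 0


class MaxPool2:
    """2x2x2 max pooling; ties share the gradient equally."""

    def forward(self, x, training=False):
        n, X, Y, Z, c = x.shape
        r = x.reshape(n, X // 2, 2, Y // 2, 2, Z // 2, 2, c)
        y = r.max(axis=(2, 4, 6))
        self._r, self._y = r, y
        return y

    def backward(self, g):
        r, y = self._r, self._y
        ymax = y[:, :, None, :, None, :, None, :]
        mask = (r == ymax).astype(np.float32)
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        gx = g[:, :, None, :, None, :, None, :] * mask / cnt
        n, c = g.shape[0], g.shape[4]
        return gx.reshape(n, g.shape[1] * 2, g.shape[2] * 2, g.shape[3] * 2, c)

    def params(self):
        return iter(())

    def n_params(self):
        return 0


def _upsample_matrix(n_in: int) -> np.ndarray:
    """Linear interpolation matrix (2n, n), cell-centered, edges clamped."""
    M = np.zeros((2 * n_in, n_in), dtype=np.float32)
    for i in range(2 * n_in):
        c = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(c))
        w = c - lo
        M[i, min(max(lo, 0), n_in - 1)] += 1.0 - w
        M[i, min(max(lo + 1, 0), n_in - 1)] += w
    return M


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_matrix_cached(n_in: int) -> np.ndarray:
    if n_in not in _UP_CACHE:
        _UP_CACHE[n_in] = _upsample_matrix(n_in)
    return _UP_CACHE[n_in]


def _apply_axis(x, M, axis):
    out = np.tensordot(M, x, axes=([1], [axis]))
    return np.moveaxis(out, 0, axis)


class TrilinearUp2:
    """Trilinear upsampling by a factor of 2 per spatial axis."""

    def forward(self, x, training=False):
        self._in_shape = x.shape
        for axis in (1, 2, 3):
            x = _apply_axis(x, _up_matrix_cached(x.shape[axis]), axis)
        return np.ascontiguousarray(x, dtype=np.float32)

    def backward(self, g):
        for axis in (1, 2, 3):
            g = _apply_axis(g, _up_matrix_cached(self._in_shape[axis]).T, axis)
        return np.ascontiguousarray(g, dtype=np.float32)

    def params(self):
        return iter(())

    def n_params(self):
        return 0


class ConvBlock:
    """conv-norm-act, twice, followed by dropout."""

    def __init__(self, cin, cout, cfg: UNetConfig, rng):
        self.layers = [
            Conv3d(cin, cout, 3, rng),
            InstanceNorm3d(cout),
            LeakyReLU(cfg.leaky_slope),
            Conv3d(cout, cout, 3, rng),
            InstanceNorm3d(cout),
            LeakyReLU(cfg.leaky_slope),
            Dropout(cfg.dropout_rate),
        ]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        for layer in self.layers:
            yield from layer.params()

    def n_params(self):
        return sum(layer.n_params() for layer in self.layers)


# ---------------------------------------------------------------------------
# U-Net


class UNet3D:
    """Encoder-decoder with skip connections and deep supervision."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f, d = cfg.base_filters, cfg.depth
        self.enc = []
        cin = cfg.in_channels
        for i in range(d):
            self.enc.append(ConvBlock(cin, f * 2**i, cfg, rng))
            cin = f * 2**i
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = ConvBlock(f * 2 ** (d - 1), f * 2**d, cfg, rng)
        self.ups, self.upconvs, self.dec = [], [], []
        deeper = f * 2**d
        for i in reversed(range(d)):  # decoder level i at resolution /2**i
            self.ups.append(TrilinearUp2())
            self.upconvs.append(Conv3d(deeper, f * 2**i, 3, rng))
            self.dec.append(ConvBlock(2 * f * 2**i, f * 2**i, cfg, rng))
            deeper = f * 2**i
        self.dec_levels = list(reversed(range(d)))  # level of each decoder entry
        self.ds_levels = [lv for lv in (2, 1) if cfg.deep_supervision and 1 <= lv <= d - 1]
        self.heads = {lv: Conv3d(f * 2**lv, cfg.out_channels, 1, rng) for lv in self.ds_levels}
        self.heads[0] = Conv3d(f, cfg.out_channels, 1, rng)
        self.ds_ups = {lv: TrilinearUp2() for lv in self.ds_levels}

    # -- plumbing ----------------------------------------------------------

    def set_dropout_rng(self, rng) -> None:
        for layer in self._all_layers():
            if isinstance(layer, Dropout):
                layer.rng = rng

    def _all_layers(self):
        for block in self.enc + [self.bottleneck] + self.dec:
            yield from block.layers
        yield from self.upconvs
        yield from self.heads.values()

    def params(self):
        for block in self.enc:
            yield from block.params()
        yield from self.bottleneck.params()
        for up_conv, block in zip(self.upconvs, self.dec):
            yield from up_conv.params()
            yield from block.params()
        for lv in sorted(self.heads):
            yield from self.heads[lv].params()

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def n_params(self) -> int:
        total = sum(b.n_params() for b in self.enc) + self.bottleneck.n_params()
        total += sum(c.n_params() for c in self.upconvs)
        total += sum(b.n_params() for b in self.dec)
        total += sum(h.n_params() for h in self.heads.values())
        return total

    def architecture_table(self) -> list[str]:
        """Human-readable layer recipe (used to hand-count parameters)."""
        rows = []
        f, d = self.cfg.base_filters, self.cfg.depth
        cin = self.cfg.in_channels
        for i in range(d):
            rows.append(f"enc{i}: block {cin}->{f * 2**i} (2x conv3+IN)")
            cin = f * 2**i
        rows.append(f"bottleneck: block {f * 2**(d-1)}->{f * 2**d}")
        deeper = f * 2**d
        for i in reversed(range(d)):
            rows.append(
                f"dec{i}: up + conv3 {deeper}->{f * 2**i}, block {2 * f * 2**i}->{f * 2**i}"
            )
            deeper = f * 2**i
        for lv in sorted(self.heads, reverse=True):
            rows.append(f"head{lv}: conv1 {self.heads[lv].cin}->{self.cfg.out_channels}")
        return rows

    # -- forward / backward ------------------------------------------------

    def forward(self, x, training: bool = False):
        """Map ``(N, in_channels, X, Y, Z)`` to per-channel probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, X, Y, Z) input, got {x.shape}"
            )
        div = 2**self.cfg.depth
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by 2**depth={div}"
            )
        h = np.ascontiguousarray(np.moveaxis(x, 1, 4))  # to channels-last
        skips = []
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        dec_outs = {}
        self._skip_channels = []
        for j, lv in enumerate(self.dec_levels):
            h = self.ups[j].forward(h, training)
            h = self.upconvs[j].forward(h, training)
            self._skip_channels.append(skips[lv].shape[4])
            h = np.concatenate([skips[lv], h], axis=4)
            h = self.dec[j].forward(h, training)
            dec_outs[lv] = h
        logits = self.heads[0].forward(dec_outs[0], training)
        if self.ds_levels:
            # Isensee-style: coarse segmentation logits are upsampled and
            # summed level by level into the final logits
            carry = None
            for lv in sorted(self.ds_levels, reverse=True):
                s = self.heads[lv].forward(dec_outs[lv], training)
                if carry is not None:
                    s = s + carry
                carry = self.ds_ups[lv].forward(s, training)
            logits = logits + carry
        self._probs = 1.0 / (1.0 + np.exp(-logits))
        return np.ascontiguousarray(np.moveaxis(self._probs, 4, 1))

    def backward(self, gprob):
        """Backpropagate a gradient wrt the output probabilities
        (``gprob`` channels-first like the forward output)."""
        gprob = np.ascontiguousarray(np.moveaxis(np.asarray(gprob, dtype=np.float32), 1, 4))
        p = self._probs
        g = (gprob * p * (1.0 - p)).astype(np.float32)
        gdec = {lv: None for lv in self.dec_levels}
        gdec[0] = self.heads[0].backward(g)
        if self.ds_levels:
            carry = g
            for lv in sorted(self.ds_levels):
                carry = self.ds_ups[lv].backward(carry)
                gh = self.heads[lv].backward(carry)
                gdec[lv] = gh if gdec[lv] is None else gdec[lv] + gh
        gskips = {}
        gdeeper = None
        for j, lv in list(enumerate(self.dec_levels))[::-1]:
            gh = gdec[lv]
            if gdeeper is not None:
                gh = gh + gdeeper
            gcat = self.dec[j].backward(gh)
            n_skip = self._skip_channels[j]
            gskips[lv] = gcat[..., :n_skip]
            gup = np.ascontiguousarray(gcat[..., n_skip:])
            gup = self.upconvs[j].backward(gup)
            gdeeper = self.ups[j].backward(gup)
        g = self.bottleneck.backward(gdeeper)
        for i in reversed(range(self.cfg.depth)):
            g = self.pools[i].backward(g)
            g = g + gskips[i]
            g = self.enc[i].backward(g)
        return np.ascontiguousarray(np.moveaxis(g, 4, 1))


def build_unet(cfg: UNetConfig, seed: int = 0) -> UNet3D:
    """Construct a randomly initialized modified 3D U-Net."""
    return UNet3D(cfg, seed=seed)


def forward_infer(model: UNet3D, patch: np.ndarray) -> np.ndarray:
    """Deterministic inference (dropout off) on a single ``(C, X, Y, Z)`` patch."""
    return model.forward(patch[None], training=False)[0]
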