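"""Compact NumPy neural-network toolkit used by the diagnosis model.

Implements exactly the layers the instance scorer and the fusion
perceptron need — 3x3 convolutions, ReLU, residual blocks, global average
pooling, dense layers — with hand-written backpropagation and an Adam
optimizer. Everything runs in float32 on the CPU; all parameter
initialization is driven by an explicit RNG so training is reproducible
bit-for-bit for a fixed seed on a fixed build.

Convolutions use a shift-and-GEMM scheme: feature maps are kept in
``(C, N, H, W)`` layout so each of the nine kernel taps is one contiguous
``(C_out, C_in) @ (C_in, N*H*W)`` matrix product — much faster in NumPy
than an im2col gather for the small channel counts used here.

Gradient correctness is enforced by finite-difference tests rather than by
construction, so keep forward and backward of each layer side by side when
editing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "Dense", "ResidualBlock", "IntensityNet", "FusionMLP", "Adam"]

_F32 = np.float32
_TAPS = [(ki, kj) for ki in range(3) for kj in range(3)]


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F32)


class Conv2d:
    """3x3 convolution, padding 1, configurable stride, with bias.

    Operates on tensors in ``(C, N, H, W)`` layout. The weight tensor is
    stored as ``(9, C_out, C_in)``, one slice per kernel tap.
    """

    def __init__(self, c_in, c_out, stride=1, rng=None):
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.W = _he_init(rng, (9, c_out, c_in), c_in * 9)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        c, n, h, w = x.shape
        s = self.stride
        ho, wo = h // s, w // s
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        taps = []
        out = np.zeros((self.c_out, n * ho * wo), dtype=x.dtype)
        for t, (ki, kj) in enumerate(_TAPS):
            xs = np.ascontiguousarray(
                xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
            ).reshape(c, -1)
            taps.append(xs)
            out += self.W[t] @ xs
        out += self.b[:, None]
        self._cache = (taps, (c, n, h, w), (ho, wo))
        return out.reshape(self.c_out, n, ho, wo)

    def backward(self, dout):
        taps, (c, n, h, w), (ho, wo) = self._cache
        s = self.stride
        dflat = dout.reshape(self.c_out, -1)
        self.db += dflat.sum(axis=1)
        dxp = np.zeros((c, n, h + 2, w + 2), dtype=dout.dtype)
        for t, (ki, kj) in enumerate(_TAPS):
            self.dW[t] += dflat @ taps[t].T
            dxs = (self.W[t].T @ dflat).reshape(c, n, ho, wo)
            dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dxs
        return dxp[:, :, 1 : h + 1, 1 : w + 1]


class Dense:
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = _he_init(rng, (d_out, d_in), d_in)
        self.b = np.zeros(d_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W


class _ReLU:
    """Leaky rectifier (slope 0.1 on the negative side).

    The small negative slope keeps gradient flowing through units that a
    hard rectifier would silence — in this small float32 network dead
    units were a measurable source of seed-to-seed instability.
    """

    slope = 0.1

    def __init__(self):
        self._m = None

    def forward(self, x):
        self._m = np.where(x > 0, x.dtype.type(1), x.dtype.type(self.slope))
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class ResidualBlock:
    """y = relu(x + conv_b(relu(conv_a(x)))), channel-preserving."""

    def __init__(self, channels, rng=None):
        self.conv_a = Conv2d(channels, channels, rng=rng)
        self.conv_b = Conv2d(channels, channels, rng=rng)
        self.r1 = _ReLU()
        self.r2 = _ReLU()

    def params(self):
        return self.conv_a.params() + self.conv_b.params()

    def forward(self, x):
        h = self.r1.forward(self.conv_a.forward(x))
        return self.r2.forward(x + self.conv_b.forward(h))

    def backward(self, dout):
        d = self.r2.backward(dout)
        dh = self.conv_b.backward(d)
        dx = self.conv_a.backward(self.r1.backward(dh))
        return dx + d


class IntensityNet:
    """Residual CNN mapping a (1, H, W) patch to a scalar metastasis logit.

    Three residual stages on a strided stem: 8 channels at H/2, then 16
    channels at H/4 for two further stages. Global average pooling feeds a
    single linear output. The post-activation maps of the last residual
    stage are exposed for class-activation heatmaps.
    """

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.stem = Conv2d(1, 8, stride=2, rng=rng)
        self.stem_relu = _ReLU()
        self.res1 = ResidualBlock(8, rng=rng)
        self.down = Conv2d(8, 16, stride=2, rng=rng)
        self.down_relu = _ReLU()
        self.res2 = ResidualBlock(16, rng=rng)
        self.res3 = ResidualBlock(16, rng=rng)
        self.fc = Dense(16, 1, rng=rng)
        self._feat = None  # (C, N, H/4, W/4) internal layout

    def params(self):
        return (
            self.stem.params()
            + self.res1.params()
            + self.down.params()
            + self.res2.params()
            + self.res3.params()
            + self.fc.params()
        )

    def forward(self, x):
        """x: (N, 1, H, W) float32 -> logits (N,)."""
        h = np.ascontiguousarray(np.asarray(x).transpose(1, 0, 2, 3))
        h = self.stem_relu.forward(self.stem.forward(h))
        h = self.res1.forward(h)
        h = self.down_relu.forward(self.down.forward(h))
        h = self.res2.forward(h)
        h = self.res3.forward(h)
        self._feat = h
        self._hw = h.shape[2] * h.shape[3]
        g = h.mean(axis=(2, 3)).T  # (N, C)
        return self.fc.forward(g)[:, 0]

    def backward(self, dlogits, to_features_only=False):
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(features) if asked.

        The returned feature gradient (and :attr:`feature_maps`) use the
        conventional ``(N, C, h, w)`` layout.
        """
        dg = self.fc.backward(np.asarray(dlogits)[:, None])  # (N, C)
        c, n = self._feat.shape[0], self._feat.shape[1]
        hs, ws = self._feat.shape[2], self._feat.shape[3]
        dh = np.broadcast_to(
            dg.T[:, :, None, None] / self._hw, (c, n, hs, ws)
        ).astype(dg.dtype)
        if to_features_only:
            return dh.transpose(1, 0, 2, 3)
        dh = self.res3.backward(dh)
        dh = self.res2.backward(dh)
        dh = self.down.backward(self.down_relu.backward(dh))
        dh = self.res1.backward(dh)
        return self.stem.backward(self.stem_relu.backward(dh))

    @property
    def feature_maps(self):
        """Last residual stage's post-activation maps, ``(N, C, h, w)``."""
        return self._feat.transpose(1, 0, 2, 3)

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0

    def state(self):
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state):
        for (p, _), s in zip(self.params(), state):
            p[...] = s


class FusionMLP:
    """One-hidden-layer perceptron mapping a node feature vector to a logit."""

    def __init__(self, d_in, hidden=16, seed=0):
        rng = np.random.default_rng(seed)
        self.l1 = Dense(d_in, hidden, rng=rng)
        self.relu = _ReLU()
        self.l2 = Dense(hidden, 1, rng=rng)
        self.d_in = d_in

    def params(self):
        return self.l1.params() + self.l2.params()

    def forward(self, x):
        return self.l2.forward(self.relu.forward(self.l1.forward(x)))[:, 0]

    def backward(self, dlogits):
        d = self.l2.backward(np.asarray(dlogits)[:, None])
        return self.l1.backward(self.relu.backward(d))

    def set_identity(self, index, mean=0.0, scale=1.0):
        """Force the network to output feature ``index`` de-standardized.

        With input x standardized as (raw - mean) / scale, the output logit
        becomes exactly the raw feature: for the leaky rectifier,
        (g(z) - g(-z)) / (1 + slope) = z where z = scale * x[index] + mean.
        Used to make the fused scorer collapse onto the intensity scorer's
        logit.
        """
        self.l1.W[...] = 0
        self.l1.b[...] = 0
        self.l2.W[...] = 0
        self.l2.b[...] = 0
        self.l1.W[0, index] = scale
        self.l1.b[0] = mean
        self.l1.W[1, index] = -scale
        self.l1.b[1] = -mean
        gain = 1.0 / (1.0 + _ReLU.slope)
        self.l2.W[0, 0] = gain
        self.l2.W[0, 1] = -gain

    def init_near_identity(self, index, mean=0.0, scale=1.0, rng=None, eps=0.05):
        """Warm start: output ~= the de-standardized feature ``index``.

        Hidden units 0 and 1 form the exact identity pair of
        :meth:`set_identity`; the remaining units get small random weights
        so the network starts at the pass-through solution but keeps
        trainable capacity.
        """
        rng = rng or np.random.default_rng()
        self.l1.W[...] = (eps * rng.standard_normal(self.l1.W.shape)).astype(_F32)
        self.l1.b[...] = 0
        self.l2.W[...] = (eps * rng.standard_normal(self.l2.W.shape)).astype(_F32)
        self.l2.b[...] = 0
        self.l1.W[0, :] = 0
        self.l1.W[1, :] = 0
        self.l1.W[0, index] = scale
        self.l1.b[0] = mean
        self.l1.W[1, index] = -scale
        self.l1.b[1] = -mean
        gain = 1.0 / (1.0 + _ReLU.slope)
        self.l2.W[0, 0] = gain
        self.l2.W[0, 1] = -gain

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0

    def state(self):
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state):
        for (p, _), s in zip(self.params(), state):
            p[...] = s


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params, lr=3e-3, betas=(0.9, 0.999), eps=1e-8, clip_norm=5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = _F32(self.clip_norm / (total + 1e-12))
                for _, g in self.params:
                    g *= scale
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0
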