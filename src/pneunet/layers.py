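"""Trainable layers: forward passes with hand-derived backward passes.

The network is small and fixed, so rather than a generic autodiff graph
each layer caches what its backward pass needs.  Forward arithmetic is
shared with :mod:`pneunet.blocks` conventions: activations are
``(N, H, W, C)`` batches, kernels are ``(k, k, C_in, C_out)``.

Parameter naming: ``<layer>/<tensor>`` (e.g. ``stem_conv/W``).  Kernels —
conv and dense weight matrices — are the only tensors subject to L2 decay;
biases and batch-norm parameters are exempt.
"""

from __future__ import annotations

import numpy as np

from .blocks import same_padding


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: trainable params, their grads, and optional non-trainable buffers."""

    name: str

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def kernel_names(self) -> list[str]:
        """Param keys subject to L2 weight decay."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2D(Layer):
    def __init__(self, name, kernel, in_channels, out_channels, *, stride=1, dilation=1,
                 padding="same", rng=None, dtype=np.float32):
        self.name = name
        self.k, self.cin, self.cout = kernel, in_channels, out_channels
        self.stride, self.dilation, self.padding = stride, dilation, padding
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (kernel, kernel, in_channels, out_channels),
                          kernel * kernel * in_channels, dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {f"{self.name}/W": self.W, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/W": self.dW, f"{self.name}/b": self.db}

    def kernel_names(self):
        return [f"{self.name}/W"]

    def forward(self, x, train=False):
        n, h, w, _ = x.shape
        k, s, d = self.k, self.stride, self.dilation
        if self.padding == "same":
            ho, pt, pb = same_padding(h, k, s, d)
            wo, pl, pr = same_padding(w, k, s, d)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt or pb or pl or pr) else x
            self._pads = (pt, pb, pl, pr)
        else:
            span = (k - 1) * d + 1
            ho, wo = (h - span) // s + 1, (w - span) // s + 1
            xp, self._pads = x, (0, 0, 0, 0)
        self._xp, self._in_shape, self._out_hw = xp, x.shape, (ho, wo)
        y = np.zeros((n, ho, wo, self.cout), dtype=x.dtype)
        for u in range(k):
            for v in range(k):
                patch = xp[:, u * d : u * d + (ho - 1) * s + 1 : s,
                           v * d : v * d + (wo - 1) * s + 1 : s, :]
                y += patch @ self.W[u, v]
        return y + self.b

    def backward(self, dy):
        k, s, d = self.k, self.stride, self.dilation
        ho, wo = self._out_hw
        xp = self._xp
        self.db = dy.sum(axis=(0, 1, 2))
        self.dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                sl = (slice(None), slice(u * d, u * d + (ho - 1) * s + 1, s),
                      slice(v * d, v * d + (wo - 1) * s + 1, s), slice(None))
                patch = xp[sl]
                self.dW[u, v] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[sl] += dy @ self.W[u, v].T
        pt, pb, pl, pr = self._pads
        n, h, w, c = self._in_shape
        return dxp[:, pt : pt + h, pl : pl + w, :]


class DepthwiseConv2D(Layer):
    def __init__(self, name, kernel, channels, *, stride=1, dilation=1,
                 padding="same", rng=None, dtype=np.float32):
        self.name = name
        self.k, self.c = kernel, channels
        self.stride, self.dilation, self.padding = stride, dilation, padding
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (kernel, kernel, channels), kernel * kernel, dtype)
        self.b = np.zeros(channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {f"{self.name}/W": self.W, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/W": self.dW, f"{self.name}/b": self.db}

    def kernel_names(self):
        return [f"{self.name}/W"]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k, s, d = self.k, self.stride, self.dilation
        ho, pt, pb = same_padding(h, k, s, d)
        wo, pl, pr = same_padding(w, k, s, d)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt or pb or pl or pr) else x
        self._xp, self._in_shape, self._out_hw, self._pads = xp, x.shape, (ho, wo), (pt, pb, pl, pr)
        y = np.zeros((n, ho, wo, c), dtype=x.dtype)
        for u in range(k):
            for v in range(k):
                patch = xp[:, u * d : u * d + (ho - 1) * s + 1 : s,
                           v * d : v * d + (wo - 1) * s + 1 : s, :]
                y += patch * self.W[u, v]
        return y + self.b

    def backward(self, dy):
        k, s, d = self.k, self.stride, self.dilation
        ho, wo = self._out_hw
        xp = self._xp
        self.db = dy.sum(axis=(0, 1, 2))
        self.dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                sl = (slice(None), slice(u * d, u * d + (ho - 1) * s + 1, s),
                      slice(v * d, v * d + (wo - 1) * s + 1, s), slice(None))
                self.dW[u, v] = (xp[sl] * dy).sum(axis=(0, 1, 2))
                dxp[sl] += dy * self.W[u, v]
        pt, pb, pl, pr = self._pads
        n, h, w, c = self._in_shape
        return dxp[:, pt : pt + h, pl : pl + w, :]


class BatchNorm(Layer):
    """Channel-wise batch normalization on (N, H, W, C) activations.

    Training uses batch statistics and updates exponential moving
    averages; evaluation uses the moving averages.
    """

    def __init__(self, name, channels, *, momentum=0.9, eps=1e-3, dtype=np.float32):
        self.name = name
        self.c, self.momentum, self.eps = channels, momentum, eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.moving_mean = np.zeros(channels, dtype=dtype)
        self.moving_var = np.ones(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._calib: list | None = None  # [sum, sum_sq, count] during recalibration

    def params(self):
        return {f"{self.name}/gamma": self.gamma, f"{self.name}/beta": self.beta}

    def grads(self):
        return {f"{self.name}/gamma": self.dgamma, f"{self.name}/beta": self.dbeta}

    def buffers(self):
        return {f"{self.name}/moving_mean": self.moving_mean,
                f"{self.name}/moving_var": self.moving_var}

    def forward(self, x, train=False):
        axes = (0, 1, 2)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._calib is not None:
                self._calib[0] += x.sum(axis=axes, dtype=np.float64)
                self._calib[1] += np.sum(x.astype(np.float64) ** 2, axis=axes)
                self._calib[2] += x.shape[0] * x.shape[1] * x.shape[2]
            else:
                m = self.momentum
                self.moving_mean[:] = m * self.moving_mean + (1 - m) * mu
                self.moving_var[:] = m * self.moving_var + (1 - m) * var
        else:
            mu, var = self.moving_mean, self.moving_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, x.shape[0] * x.shape[1] * x.shape[2]) if train else None
        return self.gamma * xhat + self.beta

    def begin_calibration(self) -> None:
        self._calib = [0.0, 0.0, 0]

    def end_calibration(self) -> None:
        """Set the moving statistics to the exact pooled statistics of the
        calibration passes ("precise BN")."""
        s, sq, m = self._calib
        self._calib = None
        if m == 0:
            return
        mean = s / m
        self.moving_mean[:] = mean
        self.moving_var[:] = np.maximum(sq / m - mean**2, 0.0)

    def backward(self, dy):
        if self._cache is None:  # eval-mode backward (used by Grad-CAM)
            ivar = 1.0 / np.sqrt(self.moving_var + self.eps)
            return dy * self.gamma * ivar
        xhat, ivar, m = self._cache
        self.dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        self.dbeta = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))) * ivar
        return dx


class ReLU(Layer):
    def __init__(self, name):
        self.name = name

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate == 0."""

    def __init__(self, name, rate):
        self.name = name
        self.rate = rate
        self.rng: np.random.Generator | None = None  # set by the trainer

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError(f"{self.name}: dropout requires an rng in training mode")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, name, in_features, out_features, *, rng=None, dtype=np.float32):
        self.name = name
        rng = rng or np.random.default_rng(0)
        self.W = _he_init(rng, (in_features, out_features), in_features, dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {f"{self.name}/W": self.W, f"{self.name}/b": self.b}

    def grads(self):
        return {f"{self.name}/W": self.dW, f"{self.name}/b": self.db}

    def kernel_names(self):
        return [f"{self.name}/W"]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class SEBlock(Layer):
    """Squeeze-and-excitation gating: GAP -> Dense(u) -> ReLU -> Dense(C)
    -> sigmoid -> channel-wise multiply."""

    def __init__(self, name, channels, squeeze_units, *, rng=None, dtype=np.float32):
        self.name = name
        self.c, self.u = channels, squeeze_units
        rng = rng or np.random.default_rng(0)
        self.w1 = _he_init(rng, (channels, squeeze_units), channels, dtype)
        self.b1 = np.zeros(squeeze_units, dtype=dtype)
        self.w2 = _he_init(rng, (squeeze_units, channels), squeeze_units, dtype)
        self.b2 = np.zeros(channels, dtype=dtype)
        for p in ("w1", "b1", "w2", "b2"):
            setattr(self, "d" + p, np.zeros_like(getattr(self, p)))

    def params(self):
        return {f"{self.name}/w1": self.w1, f"{self.name}/b1": self.b1,
                f"{self.name}/w2": self.w2, f"{self.name}/b2": self.b2}

    def grads(self):
        return {f"{self.name}/w1": self.dw1, f"{self.name}/b1": self.db1,
                f"{self.name}/w2": self.dw2, f"{self.name}/b2": self.db2}

    def kernel_names(self):
        return [f"{self.name}/w1", f"{self.name}/w2"]

    def forward(self, x, train=False):
        s = x.mean(axis=(1, 2))                      # (N, C)
        z1 = s @ self.w1 + self.b1
        h = np.maximum(z1, 0)
        g = sigmoid(h @ self.w2 + self.b2)           # (N, C) gates in (0,1)
        self._cache = (x, s, z1, h, g)
        return x * g[:, None, None, :]

    def backward(self, dy):
        x, s, z1, h, g = self._cache
        hw = x.shape[1] * x.shape[2]
        dg = (dy * x).sum(axis=(1, 2))
        dz2 = dg * g * (1 - g)
        self.dw2 = h.T @ dz2
        self.db2 = dz2.sum(axis=0)
        dh = dz2 @ self.w2.T
        dz1 = np.where(z1 > 0, dh, 0)
        self.dw1 = s.T @ dz1
        self.db1 = dz1.sum(axis=0)
        ds = dz1 @ self.w1.T
        return dy * g[:, None, None, :] + ds[:, None, None, :] / hw


class LearnablePool(Layer):
    """Two-stage 1x1-conv attention head; pools (N, H, W, C) to (N, C) by
    an attention-weighted spatial sum.

    The layer divides the sum by H*W.  This constant rescaling is
    absorbed by the downstream dense head, so the model class is the
    attention-weighted sum exactly; without it the pooled features start
    at magnitude ~HW/2 and a uniform-step optimizer responds by crushing
    the attention gate to zero instead of training the trunk.
    """

    def __init__(self, name, in_channels, hidden_channels, *, rng=None, dtype=np.float32):
        self.name = name
        self.cin, self.hidden = in_channels, hidden_channels
        rng = rng or np.random.default_rng(0)
        self.w_hidden = _he_init(rng, (in_channels, hidden_channels), in_channels, dtype)
        self.b_hidden = np.zeros(hidden_channels, dtype=dtype)
        self.w_score = _he_init(rng, (hidden_channels, 1), hidden_channels, dtype)
        self.b_score = np.zeros(1, dtype=dtype)
        for p in ("w_hidden", "b_hidden", "w_score", "b_score"):
            setattr(self, "d" + p, np.zeros_like(getattr(self, p)))
        self.attention_map: np.ndarray | None = None  # (N, H, W), exposed for inspection

    def params(self):
        return {f"{self.name}/w_hidden": self.w_hidden, f"{self.name}/b_hidden": self.b_hidden,
                f"{self.name}/w_score": self.w_score, f"{self.name}/b_score": self.b_score}

    def grads(self):
        return {f"{self.name}/w_hidden": self.dw_hidden, f"{self.name}/b_hidden": self.db_hidden,
                f"{self.name}/w_score": self.dw_score, f"{self.name}/b_score": self.db_score}

    def kernel_names(self):
        return [f"{self.name}/w_hidden", f"{self.name}/w_score"]

    def forward(self, x, train=False):
        hid = x @ self.w_hidden + self.b_hidden
        score = hid @ self.w_score + self.b_score      # (N, H, W, 1)
        attn = sigmoid(score[..., 0])                  # (N, H, W)
        self._cache = (x, hid, attn)
        self.attention_map = attn
        hw = x.shape[1] * x.shape[2]
        return np.einsum("nijc,nij->nc", x, attn) / hw

    def backward(self, dy):
        x, hid, attn = self._cache
        dy = dy / (x.shape[1] * x.shape[2])
        dx = dy[:, None, None, :] * attn[..., None]
        dattn = np.einsum("nc,nijc->nij", dy, x)
        dscore = (dattn * attn * (1 - attn))[..., None]
        self.dw_score = np.tensordot(hid, dscore, axes=([0, 1, 2], [0, 1, 2]))
        self.db_score = dscore.sum(axis=(0, 1, 2))
        dhid = dscore @ self.w_score.T
        self.dw_hidden = np.tensordot(x, dhid, axes=([0, 1, 2], [0, 1, 2]))
        self.db_hidden = dhid.sum(axis=(0, 1, 2))
        return dx + dhid @ self.w_hidden.T


class GlobalAveragePool(Layer):
    """Fixed per-channel spatial mean (the GAP ablation of learnable pooling)."""

    def __init__(self, name):
        self.name = name
        self.attention_map = None

    def forward(self, x, train=False):
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / self._hw
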