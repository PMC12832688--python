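"""Pure-numeric building blocks of the PneuNet architecture.

Every operation here is a plain function on numpy arrays with explicitly
supplied weights, independent of the training machinery, so each block's
contract (cost formulas, dilated convolution, squeeze-and-excitation
gating, ASPP fusion, learnable attention pooling) can be tested in
isolation.  Feature maps are rank-3 arrays indexed ``(row, col, channel)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvSpec",
    "SEConfig",
    "ASPPConfig",
    "LearnablePoolingConfig",
    "SEWeights",
    "ASPPWeights",
    "LearnablePoolWeights",
    "PoolResult",
    "standard_conv_cost",
    "separable_conv_cost",
    "atrous_conv_1d",
    "conv2d",
    "depthwise_conv2d",
    "same_padding",
    "se_squeeze",
    "se_block",
    "aspp",
    "learnable_pool",
    "gap_pool",
    "as_feature_map",
]


# ---------------------------------------------------------------------------
# configuration records


@dataclass(frozen=True)
class ConvSpec:
    """Declarative description of a single convolution.

    ``kernel`` is the spatial kernel side k; ``dilation`` the atrous rate r.
    ``depthwise`` convolutions act per channel and therefore require
    ``out_channels == in_channels``.
    """

    kernel: int
    in_channels: int
    out_channels: int
    stride: int = 1
    dilation: int = 1
    bias: bool = True
    depthwise: bool = False
    padding: str = "same"

    def __post_init__(self) -> None:
        if min(self.kernel, self.in_channels, self.out_channels) < 1:
            raise ValueError("kernel and channel counts must be positive")
        if self.stride < 1 or self.dilation < 1:
            raise ValueError("stride and dilation must be >= 1")
        if self.depthwise and self.out_channels != self.in_channels:
            raise ValueError("depthwise convolution requires out_channels == in_channels")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {self.padding!r}")


@dataclass(frozen=True)
class SEConfig:
    """Squeeze-and-excitation bottleneck: ``channels`` gated through
    ``squeeze_units`` hidden units."""

    channels: int = 128
    squeeze_units: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.squeeze_units < self.channels:
            raise ValueError("squeeze_units must satisfy 0 < squeeze_units < channels")


@dataclass(frozen=True)
class ASPPConfig:
    """Atrous spatial pyramid: one 1x1 branch plus a 3x3 branch per
    dilation rate, concatenated and fused back by a 1x1 convolution."""

    in_channels: int = 128
    branch_channels: int = 32
    dilation_rates: tuple[int, ...] = (1, 3, 6)
    fuse_channels: int = 128

    def __post_init__(self) -> None:
        rates = tuple(self.dilation_rates)
        if any(r < 1 for r in rates) or list(rates) != sorted(set(rates)):
            raise ValueError("dilation_rates must be strictly increasing positive integers")
        object.__setattr__(self, "dilation_rates", rates)

    @property
    def concat_channels(self) -> int:
        return self.branch_channels * (1 + len(self.dilation_rates))


@dataclass(frozen=True)
class LearnablePoolingConfig:
    """Two-stage 1x1-convolution attention head producing a sigmoid map A
    over spatial positions; features are summed weighted by A."""

    in_channels: int = 128
    hidden_channels: int = 128


# ---------------------------------------------------------------------------
# weight containers (plain arrays, loadable from a checkpoint)


@dataclass
class SEWeights:
    w1: np.ndarray  # (channels, squeeze_units)
    b1: np.ndarray  # (squeeze_units,)
    w2: np.ndarray  # (squeeze_units, channels)
    b2: np.ndarray  # (channels,)


@dataclass
class ASPPWeights:
    branch_kernels: list[np.ndarray]  # each (k, k, in_channels, branch_channels)
    branch_biases: list[np.ndarray]
    fuse_kernel: np.ndarray  # (1, 1, concat_channels, fuse_channels)
    fuse_bias: np.ndarray


@dataclass
class LearnablePoolWeights:
    w_hidden: np.ndarray  # (1, 1, in_channels, hidden_channels)
    b_hidden: np.ndarray
    w_score: np.ndarray  # (1, 1, hidden_channels, 1)
    b_score: np.ndarray


@dataclass
class PoolResult:
    """Pooled feature vector together with the spatial attention map A."""

    pooled: np.ndarray  # (channels,)
    attention_map: np.ndarray  # (H, W)


# ---------------------------------------------------------------------------
# helpers


def as_feature_map(fm: np.ndarray) -> np.ndarray:
    """Validate and return a rank-3 (H, W, C) feature map."""
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError(f"feature map must be rank 3 (H, W, C), got shape {fm.shape}")
    if min(fm.shape) < 1:
        raise ValueError(f"feature map dimensions must be positive, got {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ValueError("feature map contains non-finite values")
    return fm


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def same_padding(size: int, kernel: int, stride: int, dilation: int) -> tuple[int, int, int]:
    """Return (out_size, pad_before, pad_after) for same-padding arithmetic.

    Output size is ceil(size / stride); total padding splits with the extra
    pixel trailing (the usual convention for stride-2 downsampling).
    """
    out = -(-size // stride)
    span = (kernel - 1) * dilation + 1
    total = max((out - 1) * stride + span - size, 0)
    return out, total // 2, total - total // 2


# ---------------------------------------------------------------------------
# complexity audit


def standard_conv_cost(spec: ConvSpec) -> int:
    """Multiply-accumulates per spatial position of a standard convolution:
    k^2 * C_in * C_out."""
    if spec.depthwise:
        raise ValueError("standard_conv_cost is undefined for depthwise convolutions")
    return spec.kernel**2 * spec.in_channels * spec.out_channels


def separable_conv_cost(spec: ConvSpec) -> int:
    """Multiply-accumulates per spatial position of the depthwise-separable
    factorization: k^2 * C_in (spatial) + C_in * C_out (pointwise)."""
    return spec.kernel**2 * spec.in_channels + spec.in_channels * spec.out_channels


# ---------------------------------------------------------------------------
# convolution primitives


def atrous_conv_1d(signal: np.ndarray, weights: np.ndarray, rate: int) -> np.ndarray:
    """Valid-mode 1-D dilated convolution y[i] = sum_k x[i + r*k] * w[k].

    Serves as the reference oracle for the 2-D dilated convolutions used
    in the ASPP module.
    """
    x = np.asarray(signal, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if x.ndim != 1 or w.ndim != 1:
        raise ValueError("signal and weights must be 1-D")
    if rate < 1:
        raise ValueError("dilation rate must be >= 1")
    span = (w.size - 1) * rate + 1
    if x.size < span:
        raise ValueError(
            f"signal of length {x.size} too short for kernel span {span} "
            f"(|weights|={w.size}, rate={rate})"
        )
    n_out = x.size - span + 1
    y = np.zeros(n_out)
    for k in range(w.size):
        y += x[k * rate : k * rate + n_out] * w[k]
    return y


def conv2d(
    x: np.ndarray,
    kernel: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: str = "same",
) -> np.ndarray:
    """2-D convolution (cross-correlation) on (..., H, W, C_in) input.

    ``kernel`` has shape (k, k, C_in, C_out).  Accepts a single feature map
    (H, W, C) or a batch (N, H, W, C).
    """
    x = np.asarray(x)
    single = x.ndim == 3
    if single:
        x = x[None]
    k = kernel.shape[0]
    n, h, w_in, _ = x.shape
    if padding == "same":
        ho, pt, pb = same_padding(h, k, stride, dilation)
        wo, pl, pr = same_padding(w_in, k, stride, dilation)
        x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    elif padding == "valid":
        span = (k - 1) * dilation + 1
        if h < span or w_in < span:
            raise ValueError(f"input {h}x{w_in} too small for kernel span {span}")
        ho = (h - span) // stride + 1
        wo = (w_in - span) // stride + 1
    else:
        raise ValueError(f"unknown padding {padding!r}")
    y = np.zeros((n, ho, wo, kernel.shape[3]), dtype=np.result_type(x, kernel))
    for u in range(k):
        for v in range(k):
            patch = x[:, u * dilation : u * dilation + (ho - 1) * stride + 1 : stride,
                      v * dilation : v * dilation + (wo - 1) * stride + 1 : stride, :]
            y += patch @ kernel[u, v]
    if bias is not None:
        y += bias
    return y[0] if single else y


def depthwise_conv2d(
    x: np.ndarray,
    kernel: np.ndarray,
    bias: np.ndarray | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: str = "same",
) -> np.ndarray:
    """Per-channel (depthwise) 2-D convolution; ``kernel`` is (k, k, C)."""
    x = np.asarray(x)
    single = x.ndim == 3
    if single:
        x = x[None]
    if kernel.shape[2] != x.shape[3]:
        raise ValueError("depthwise kernel channels must match input channels")
    k = kernel.shape[0]
    n, h, w_in, c = x.shape
    if padding == "same":
        ho, pt, pb = same_padding(h, k, stride, dilation)
        wo, pl, pr = same_padding(w_in, k, stride, dilation)
        x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    else:
        span = (k - 1) * dilation + 1
        ho = (h - span) // stride + 1
        wo = (w_in - span) // stride + 1
    y = np.zeros((n, ho, wo, c), dtype=np.result_type(x, kernel))
    for u in range(k):
        for v in range(k):
            patch = x[:, u * dilation : u * dilation + (ho - 1) * stride + 1 : stride,
                      v * dilation : v * dilation + (wo - 1) * stride + 1 : stride, :]
            y += patch * kernel[u, v]
    if bias is not None:
        y += bias
    return y[0] if single else y


# ---------------------------------------------------------------------------
# attention and pooling blocks


def se_squeeze(fm: np.ndarray) -> np.ndarray:
    """Squeeze step of the SE block: per-channel spatial mean
    s_c = (1 / HW) * sum_ij x_ijc."""
    fm = as_feature_map(fm)
    return fm.mean(axis=(0, 1))


def se_block(fm: np.ndarray, cfg: SEConfig, weights: SEWeights) -> np.ndarray:
    """Squeeze-and-excitation channel gating.

    Squeeze to per-channel means, pass through a rectified bottleneck of
    ``squeeze_units`` units, expand back, gate with a sigmoid in (0, 1),
    and rescale every channel of the input.  Spatial dims are unchanged.
    """
    fm = as_feature_map(fm)
    if fm.shape[2] != cfg.channels:
        raise ValueError(f"feature map has {fm.shape[2]} channels, config expects {cfg.channels}")
    s = fm.mean(axis=(0, 1))
    hidden = np.maximum(s @ weights.w1 + weights.b1, 0.0)
    gates = _sigmoid(hidden @ weights.w2 + weights.b2)
    return fm * gates


def aspp(fm: np.ndarray, cfg: ASPPConfig, weights: ASPPWeights) -> np.ndarray:
    """Atrous spatial pyramid pooling: parallel 1x1 and dilated 3x3
    branches, channel concatenation, 1x1 fusion.  Same-padding throughout,
    so spatial dims are preserved."""
    fm = as_feature_map(fm)
    if fm.shape[2] != cfg.in_channels:
        raise ValueError(f"feature map has {fm.shape[2]} channels, config expects {cfg.in_channels}")
    rates = (1,) + tuple(cfg.dilation_rates)  # rate of the 1x1 branch is irrelevant
    branches = [
        conv2d(fm, kern, b, dilation=rate, padding="same")
        for kern, b, rate in zip(weights.branch_kernels, weights.branch_biases, rates)
    ]
    cat = np.concatenate(branches, axis=-1)
    return conv2d(cat, weights.fuse_kernel, weights.fuse_bias, padding="same")


def learnable_pool(
    fm: np.ndarray, cfg: LearnablePoolingConfig, weights: LearnablePoolWeights
) -> PoolResult:
    """Trainable spatial attention pooling.

    A two-stage 1x1-convolution head maps the feature map to a scalar
    score per position; A = sigmoid(score) in (0, 1); the pooled vector is
    the unnormalized weighted sum F_pooled[c] = sum_ij F(i,j,c) * A(i,j).
    """
    fm = as_feature_map(fm)
    if fm.shape[2] != cfg.in_channels:
        raise ValueError(f"feature map has {fm.shape[2]} channels, config expects {cfg.in_channels}")
    hidden = conv2d(fm, weights.w_hidden, weights.b_hidden, padding="same")
    score = conv2d(hidden, weights.w_score, weights.b_score, padding="same")
    attn = _sigmoid(score[..., 0])
    pooled = np.einsum("ijc,ij->c", fm, attn)
    return PoolResult(pooled=pooled, attention_map=attn)


def gap_pool(fm: np.ndarray) -> np.ndarray:
    """Global average pooling: per-channel spatial mean (the fixed pooling
    that learnable pooling replaces; identical formula to se_squeeze)."""
    return se_squeeze(fm)
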