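"""PneuNet graph assembly, parameter auditing and checkpointing.

The architecture: a 3x3 stem convolution (32 filters), three sequential
depthwise-separable blocks whose outputs are concatenated with the stem
into a 128-channel fusion tensor, squeeze-and-excitation channel
attention, a stride-2 depthwise downsample, an atrous spatial pyramid
(rates 1/3/6) fused back to 128 channels, attention-weighted learnable
pooling (or plain GAP in the ablation), dropout, and a single sigmoid
unit.  Batch normalization follows every convolution.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .blocks import ConvSpec, separable_conv_cost, standard_conv_cost
from .layers import (
    BatchNorm,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    Dropout,
    GlobalAveragePool,
    Layer,
    LearnablePool,
    ReLU,
    SEBlock,
    sigmoid,
)

__all__ = [
    "ArchitectureConfig",
    "LayerSpec",
    "ParamReport",
    "PneuNet",
    "build_pneunet",
    "count_parameters",
    "param_report",
    "complexity_report",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    input_height: int = 224
    input_width: int = 224
    input_channels: int = 3
    stem_filters: int = 32
    fusion_branches: int = 4  # stem + three depthwise-separable blocks
    pooling_mode: str = "learnable"  # or "gap"
    dropout_rate: float = 0.3
    se_squeeze_units: int = 8
    aspp_branch_channels: int = 32
    dilation_rates: tuple[int, ...] = (1, 3, 6)

    def __post_init__(self) -> None:
        if self.pooling_mode not in ("learnable", "gap"):
            raise ValueError(f"pooling_mode must be 'learnable' or 'gap', got {self.pooling_mode!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.fusion_branches * self.stem_filters != 128:
            raise ValueError("fusion_branches x stem_filters must equal 128")
        object.__setattr__(self, "dilation_rates", tuple(self.dilation_rates))

    @property
    def fused_channels(self) -> int:
        return self.fusion_branches * self.stem_filters


@dataclass(frozen=True)
class LayerSpec:
    """Declarative layer description used for parameter auditing."""

    name: str
    kind: str  # conv | depthwise_conv | dense | batch_norm | se_block | learnable_pool | concat | dropout | activation | gap
    conv_spec: ConvSpec | None = None
    in_features: int = 0
    out_features: int = 0
    channels: int = 0
    squeeze_units: int = 0
    hidden_channels: int = 0


@dataclass
class ParamReport:
    rows: list[tuple[str, int]]
    total: int

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.rows, columns=["layer", "params"])
        df.loc[len(df)] = ["total", self.total]
        df.to_csv(path, index=False)

    def __str__(self) -> str:
        width = max(len(n) for n, _ in self.rows + [("total", 0)])
        lines = [f"{n:<{width}}  {p:>10,}" for n, p in self.rows]
        lines.append(f"{'total':<{width}}  {self.total:>10,}")
        return "\n".join(lines)


def count_parameters(layer: LayerSpec) -> int:
    """Trainable parameters of one layer by standard arithmetic.

    conv: k^2*C_in*C_out + C_out; depthwise: k^2*C + C; dense: in*out + out;
    batch norm: 2C; SE block: (C*u + u) + (u*C + C); learnable pooling:
    (C*h + h) + (h + 1) from its two-stage 1x1 head.
    """
    if layer.kind == "conv":
        s = layer.conv_spec
        return s.kernel**2 * s.in_channels * s.out_channels + (s.out_channels if s.bias else 0)
    if layer.kind == "depthwise_conv":
        s = layer.conv_spec
        return s.kernel**2 * s.in_channels + (s.in_channels if s.bias else 0)
    if layer.kind == "dense":
        return layer.in_features * layer.out_features + layer.out_features
    if layer.kind == "batch_norm":
        return 2 * layer.channels
    if layer.kind == "se_block":
        c, u = layer.channels, layer.squeeze_units
        return (c * u + u) + (u * c + c)
    if layer.kind == "learnable_pool":
        c, h = layer.channels, layer.hidden_channels
        return (c * h + h) + (h * 1 + 1)
    if layer.kind in ("concat", "dropout", "activation", "gap"):
        return 0
    raise ValueError(f"unknown layer kind {layer.kind!r}")


class PneuNet:
    """The assembled network with explicit forward and backward passes.

    ``forward`` records every named stage activation in ``activations``;
    ``backward`` computes parameter gradients and can capture the gradient
    flowing into any spatial stage (used by Grad-CAM).
    """

    #: stages with spatial extent usable as Grad-CAM targets
    SPATIAL_STAGES = ("stem", "block1", "block2", "block3", "concat", "se", "down", "aspp")

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = cfg.stem_filters
        fused = cfg.fused_channels
        bc = cfg.aspp_branch_channels

        self.stem_conv = Conv2D("stem_conv", 3, cfg.input_channels, c, rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm("stem_bn", c, dtype=dtype)
        self.stem_relu = ReLU("stem_relu")

        self.n_blocks = cfg.fusion_branches - 1
        self.blocks: list[dict[str, Layer]] = []
        for i in range(1, self.n_blocks + 1):
            self.blocks.append({
                "dw": DepthwiseConv2D(f"block{i}_dw", 3, c, rng=rng, dtype=dtype),
                "dw_bn": BatchNorm(f"block{i}_dw_bn", c, dtype=dtype),
                "dw_relu": ReLU(f"block{i}_dw_relu"),
                "pw": Conv2D(f"block{i}_pw", 1, c, c, rng=rng, dtype=dtype),
                "pw_bn": BatchNorm(f"block{i}_pw_bn", c, dtype=dtype),
                "pw_relu": ReLU(f"block{i}_pw_relu"),
                "drop": Dropout(f"block{i}_dropout", cfg.dropout_rate),
            })

        self.se = SEBlock("se", fused, cfg.se_squeeze_units, rng=rng, dtype=dtype)
        self.down_dw = DepthwiseConv2D("down_dw", 3, fused, stride=2, rng=rng, dtype=dtype)
        self.down_bn = BatchNorm("down_bn", fused, dtype=dtype)
        self.down_relu = ReLU("down_relu")

        self.aspp_branches: list[dict[str, Layer]] = []
        specs = [("aspp_branch_1x1", 1, 1)] + [
            (f"aspp_branch_r{r}", 3, r) for r in cfg.dilation_rates
        ]
        for name, k, rate in specs:
            self.aspp_branches.append({
                "conv": Conv2D(name, k, fused, bc, dilation=rate, rng=rng, dtype=dtype),
                "bn": BatchNorm(f"{name}_bn", bc, dtype=dtype),
                "relu": ReLU(f"{name}_relu"),
            })
        concat_ch = bc * len(specs)
        self.aspp_fuse = Conv2D("aspp_fuse", 1, concat_ch, fused, rng=rng, dtype=dtype)
        self.aspp_fuse_bn = BatchNorm("aspp_fuse_bn", fused, dtype=dtype)
        self.aspp_fuse_relu = ReLU("aspp_fuse_relu")

        if cfg.pooling_mode == "learnable":
            self.pool: Layer = LearnablePool("learnable_pooling", fused, fused, rng=rng, dtype=dtype)
        else:
            self.pool = GlobalAveragePool("gap")
        self.head_drop = Dropout("head_dropout", cfg.dropout_rate)
        self.classifier = Dense("classifier", fused, 1, rng=rng, dtype=dtype)
        # attention-sum pooling yields features of magnitude ~HW/2, so a
        # fan-in-scaled head would start deeply saturated; a zero head
        # starts every probability at 0.5 and learns its own scale
        self.classifier.W[...] = 0.0

        self.activations: dict[str, np.ndarray] = {}
        self._stage_grads: dict[str, np.ndarray] = {}

    # -- layer bookkeeping -------------------------------------------------

    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = [self.stem_conv, self.stem_bn]
        for blk in self.blocks:
            layers += [blk["dw"], blk["dw_bn"], blk["pw"], blk["pw_bn"], blk["drop"]]
        layers += [self.se, self.down_dw, self.down_bn]
        for br in self.aspp_branches:
            layers += [br["conv"], br["bn"]]
        layers += [self.aspp_fuse, self.aspp_fuse_bn, self.pool, self.head_drop, self.classifier]
        return layers

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._all_layers():
            out.update(layer.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._all_layers():
            out.update(layer.grads())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._all_layers():
            out.update(layer.buffers())
        return out

    def kernel_names(self) -> list[str]:
        names: list[str] = []
        for layer in self._all_layers():
            names += layer.kernel_names()
        return names

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for blk in self.blocks:
            blk["drop"].rng = rng
        self.head_drop.rng = rng

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        current = self.params()
        for key, arr in values.items():
            if key not in current:
                raise KeyError(f"unknown parameter {key!r}")
            if current[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {current[key].shape} vs {arr.shape}")
            current[key][...] = arr

    def set_buffers(self, values: dict[str, np.ndarray]) -> None:
        current = self.buffers()
        for key, arr in values.items():
            current[key][...] = arr

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run a batch (N, H, W, C) through the network; returns (N,) pneumonia
        probabilities.  Stage activations are stored in ``self.activations``."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        acts = self.activations = {}
        t = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x, train), train))
        acts["stem"] = t
        outs = [t]
        for i, blk in enumerate(self.blocks, start=1):
            t = blk["dw_relu"].forward(blk["dw_bn"].forward(blk["dw"].forward(t, train), train))
            t = blk["pw_relu"].forward(blk["pw_bn"].forward(blk["pw"].forward(t, train), train))
            t = blk["drop"].forward(t, train)
            acts[f"block{i}"] = t
            outs.append(t)
        cat = np.concatenate(outs, axis=-1)
        acts["concat"] = cat
        t = self.se.forward(cat, train)
        acts["se"] = t
        t = self.down_relu.forward(self.down_bn.forward(self.down_dw.forward(t, train), train))
        acts["down"] = t
        branch_outs = [
            br["relu"].forward(br["bn"].forward(br["conv"].forward(t, train), train))
            for br in self.aspp_branches
        ]
        acat = np.concatenate(branch_outs, axis=-1)
        f = self.aspp_fuse_relu.forward(
            self.aspp_fuse_bn.forward(self.aspp_fuse.forward(acat, train), train))
        acts["aspp"] = f
        v = self.pool.forward(f, train)
        acts["pooled"] = v
        if getattr(self.pool, "attention_map", None) is not None:
            acts["attention"] = self.pool.attention_map
        v = self.head_drop.forward(v, train)
        logit = self.classifier.forward(v, train)[:, 0]
        acts["logit"] = logit
        p = sigmoid(logit)
        acts["prob"] = p
        return p

    def backward(self, dlogit: np.ndarray, capture: str | None = None) -> dict[str, np.ndarray]:
        """Backpropagate from d loss / d logit (shape (N,)).

        Fills every layer's gradients and returns them as a dict.  If
        ``capture`` names a spatial stage, the gradient at that stage's
        output is stored in ``self._stage_grads[capture]``.
        """
        self._stage_grads = {}
        g = self.classifier.backward(np.asarray(dlogit, dtype=self.dtype)[:, None])
        g = self.head_drop.backward(g)
        g = self.pool.backward(g)
        if capture == "aspp":
            self._stage_grads["aspp"] = g
        g = self.aspp_fuse.backward(self.aspp_fuse_bn.backward(self.aspp_fuse_relu.backward(g)))
        bc = self.cfg.aspp_branch_channels
        gd = np.zeros_like(self.activations["down"])
        for j, br in enumerate(self.aspp_branches):
            gb = g[..., j * bc : (j + 1) * bc]
            gd += br["conv"].backward(br["bn"].backward(br["relu"].backward(gb)))
        if capture == "down":
            self._stage_grads["down"] = gd
        g = self.down_dw.backward(self.down_bn.backward(self.down_relu.backward(gd)))
        if capture == "se":
            self._stage_grads["se"] = g
        g = self.se.backward(g)
        if capture == "concat":
            self._stage_grads["concat"] = g
        c = self.cfg.stem_filters
        chunks = [g[..., j * c : (j + 1) * c] for j in range(self.cfg.fusion_branches)]
        carry = np.zeros_like(chunks[-1])
        for i in range(self.n_blocks, 0, -1):
            blk = self.blocks[i - 1]
            gi = chunks[i] + carry
            if capture == f"block{i}":
                self._stage_grads[f"block{i}"] = gi
            gi = blk["drop"].backward(gi)
            gi = blk["pw"].backward(blk["pw_bn"].backward(blk["pw_relu"].backward(gi)))
            carry = blk["dw"].backward(blk["dw_bn"].backward(blk["dw_relu"].backward(gi)))
        gstem = chunks[0] + carry
        if capture == "stem":
            self._stage_grads["stem"] = gstem
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(gstem)))
        return self.grads()

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 32,
                       max_batches: int = 8) -> None:
        """Recompute every batch-norm layer's moving statistics exactly
        under the current weights ("precise BN").

        Desk-scale runs take few optimizer steps per epoch, so exponential
        moving averages lag the weights badly; evaluating with lagged
        statistics compresses the logits toward a constant.  This pass
        runs up to ``max_batches`` batches forward with batch-statistic
        normalization (dropout disabled) and pools the statistics.
        """
        bns = [ly for ly in self._all_layers() if isinstance(ly, BatchNorm)]
        drops = [blk["drop"] for blk in self.blocks] + [self.head_drop]
        rates = [d.rate for d in drops]
        for d in drops:
            d.rate = 0.0
        for bn in bns:
            bn.begin_calibration()
        try:
            for i in range(0, min(len(x), max_batches * batch_size), batch_size):
                self.forward(x[i : i + batch_size], train=True)
        finally:
            for bn in bns:
                bn.end_calibration()
            for d, r in zip(drops, rates):
                d.rate = r

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Eval-mode probabilities for a stack of inputs."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        return np.concatenate(
            [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)])

    # -- audits ------------------------------------------------------------

    def layer_specs(self) -> list[LayerSpec]:
        cfg = self.cfg
        c, fused, bc = cfg.stem_filters, cfg.fused_channels, cfg.aspp_branch_channels
        specs = [
            LayerSpec("stem_conv", "conv",
                      conv_spec=ConvSpec(3, cfg.input_channels, c)),
            LayerSpec("stem_bn", "batch_norm", channels=c),
        ]
        for i in range(1, self.n_blocks + 1):
            specs += [
                LayerSpec(f"block{i}_dw", "depthwise_conv",
                          conv_spec=ConvSpec(3, c, c, depthwise=True)),
                LayerSpec(f"block{i}_dw_bn", "batch_norm", channels=c),
                LayerSpec(f"block{i}_pw", "conv", conv_spec=ConvSpec(1, c, c)),
                LayerSpec(f"block{i}_pw_bn", "batch_norm", channels=c),
            ]
        specs += [
            LayerSpec("concat", "concat"),
            LayerSpec("se", "se_block", channels=fused, squeeze_units=cfg.se_squeeze_units),
            LayerSpec("down_dw", "depthwise_conv",
                      conv_spec=ConvSpec(3, fused, fused, stride=2, depthwise=True)),
            LayerSpec("down_bn", "batch_norm", channels=fused),
            LayerSpec("aspp_branch_1x1", "conv", conv_spec=ConvSpec(1, fused, bc)),
            LayerSpec("aspp_branch_1x1_bn", "batch_norm", channels=bc),
        ]
        for r in cfg.dilation_rates:
            specs += [
                LayerSpec(f"aspp_branch_r{r}", "conv",
                          conv_spec=ConvSpec(3, fused, bc, dilation=r)),
                LayerSpec(f"aspp_branch_r{r}_bn", "batch_norm", channels=bc),
            ]
        concat_ch = bc * (1 + len(cfg.dilation_rates))
        specs += [
            LayerSpec("aspp_fuse", "conv", conv_spec=ConvSpec(1, concat_ch, fused)),
            LayerSpec("aspp_fuse_bn", "batch_norm", channels=fused),
        ]
        if cfg.pooling_mode == "learnable":
            specs.append(LayerSpec("learnable_pooling", "learnable_pool",
                                   channels=fused, hidden_channels=fused))
        else:
            specs.append(LayerSpec("gap", "gap"))
        specs.append(LayerSpec("classifier", "dense", in_features=fused, out_features=1))
        return specs

    def stage_shapes(self) -> dict[str, tuple]:
        """Analytic output shape of every named stage (excluding batch dim)."""
        cfg = self.cfg
        h, w = cfg.input_height, cfg.input_width
        hd, wd = -(-h // 2), -(-w // 2)
        fused = cfg.fused_channels
        shapes = {"input": (h, w, cfg.input_channels), "stem": (h, w, cfg.stem_filters)}
        for i in range(1, self.n_blocks + 1):
            shapes[f"block{i}"] = (h, w, cfg.stem_filters)
        shapes.update({
            "concat": (h, w, fused),
            "se": (h, w, fused),
            "down": (hd, wd, fused),
            "aspp": (hd, wd, fused),
            "pooled": (fused,),
            "prob": (),
        })
        return shapes


def build_pneunet(cfg: ArchitectureConfig | None = None, seed: int = 0,
                  dtype=np.float32) -> PneuNet:
    """Assemble the network; two builds from the same seed are identical."""
    return PneuNet(cfg or ArchitectureConfig(), seed=seed, dtype=dtype)


def param_report(model: PneuNet) -> ParamReport:
    """Per-layer trainable parameter counts, audited from the actual
    weight arrays (so the report can never drift from the build)."""
    rows: list[tuple[str, int]] = []
    for layer in model._all_layers():
        p = layer.params()
        rows.append((layer.name, int(sum(a.size for a in p.values()))))
    return ParamReport(rows=rows, total=int(sum(n for _, n in rows)))


def complexity_report(model: PneuNet) -> list[tuple[str, int, int | None]]:
    """Per-layer multiply-accumulates per spatial position.

    Each row is (layer, standard-convolution cost, separable cost or None).
    Separable blocks report the cost of the fused standard convolution they
    replace next to the actual depthwise + pointwise cost.
    """
    cfg = model.cfg
    c, fused, bc = cfg.stem_filters, cfg.fused_channels, cfg.aspp_branch_channels
    rows: list[tuple[str, int, int | None]] = [
        ("stem_conv", standard_conv_cost(ConvSpec(3, cfg.input_channels, c)), None),
    ]
    sep = ConvSpec(3, c, c)
    for i in range(1, model.n_blocks + 1):
        rows.append((f"block{i}_separable", standard_conv_cost(sep), separable_conv_cost(sep)))
    down = ConvSpec(3, fused, fused)
    rows.append(("down_dw", standard_conv_cost(down), 3 * 3 * fused))
    rows.append(("aspp_branch_1x1", standard_conv_cost(ConvSpec(1, fused, bc)), None))
    for r in cfg.dilation_rates:
        rows.append((f"aspp_branch_r{r}", standard_conv_cost(ConvSpec(3, fused, bc, dilation=r)), None))
    concat_ch = bc * (1 + len(cfg.dilation_rates))
    rows.append(("aspp_fuse", standard_conv_cost(ConvSpec(1, concat_ch, fused)), None))
    return rows


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: PneuNet, path, *, best_epoch: int = 1,
                    val_loss_at_best: float = float("nan")) -> None:
    """Write a single .npz archive: architecture (as JSON), every trainable
    weight, batch-norm moving statistics, and checkpoint metadata."""
    arrays = {f"param::{k}": v for k, v in model.params().items()}
    arrays.update({f"buffer::{k}": v for k, v in model.buffers().items()})
    meta = {
        "architecture": asdict(model.cfg),
        "best_epoch": int(best_epoch),
        "val_loss_at_best": float(val_loss_at_best),
        "dtype": np.dtype(model.dtype).name,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[PneuNet, dict]:
    """Reconstruct a model from a checkpoint archive; returns (model, meta)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        arch = meta["architecture"]
        arch["dilation_rates"] = tuple(arch["dilation_rates"])
        cfg = ArchitectureConfig(**arch)
        model = PneuNet(cfg, seed=0, dtype=np.dtype(meta["dtype"]))
        model.set_params({k[len("param::"):]: data[k] for k in data.files
                          if k.startswith("param::")})
        model.set_buffers({k[len("buffer::"):]: data[k] for k in data.files
                           if k.startswith("buffer::")})
    return model, meta
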