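"""The feature-enhancement-guided counting network (FEG Net).

Three parts:

* **backbone** — the first ten convolution layers of VGG-16 (three max-pools),
  producing features at 1/8 of the input resolution;
* **density regression head** — four 3x3 convolutions with dilation 2 and
  channels 512/512/256/128, then a 1x1 convolution to a single-channel raw
  density ``O_d``, restored to input resolution by bilinear upsampling;
* **feature enhancement module (FEM)** — dual paths off a shared dilated 3x3
  convolution: an *unsupervised* attention path whose sigmoid output ``f``
  multiplicatively gates ``O_d`` (Den_f = O_d * f), and a *supervised* path
  emitting a foreground probability ``p`` trained against a binary mask.

Ablation variants: ``baseline1`` (no FEM, a CSRNet-style head), ``baseline2``
(attention path only), ``baseline3`` (supervised path only, no gating),
``full`` (both paths). A ``width_multiplier`` scales every channel count so a
tiny variant trains on a single CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .labels import DensityMap

VARIANTS = ("full", "baseline1", "baseline2", "baseline3")

# VGG-16 prefix: channel plan of the first ten convolutions
BACKBONE_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512]
HEAD_CHANNELS = [512, 512, 256, 128]


@dataclass
class NetworkSpec:
    """Declarative description of a FEG Net instance."""

    variant: str = "full"
    width_multiplier: float = 1.0
    dilation_rate: int = 2
    pretrained_backbone: str | None = None  # path to an .npz of VGG weights
    input_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must lie in (0, 1]")
        if self.pretrained_backbone and self.width_multiplier != 1.0:
            raise ValueError(
                "pretrained backbone weights require width_multiplier == 1 "
                "(channel shapes are fixed)"
            )

    def scale(self, channels: int) -> int:
        return max(1, math.ceil(channels * self.width_multiplier))

    @property
    def has_attention(self) -> bool:
        return self.variant in ("full", "baseline2")

    @property
    def has_supervised(self) -> bool:
        return self.variant in ("full", "baseline3")


@dataclass
class ForwardOutput:
    """All maps a forward pass produces.

    ``density`` is at input resolution; ``raw_density`` (O_d), ``attention``
    (f) and ``probability`` (p) live on the 1/8 feature grid. During training
    these are autograd tensors; call :meth:`numpy` for plain arrays.
    """

    density: Tensor          # (N, 1, H, W)
    raw_density: Tensor      # (N, 1, H/8, W/8)
    attention: Tensor | None
    probability: Tensor | None

    def numpy(self) -> "ForwardOutput":
        conv = lambda t: None if t is None else Tensor(t.data.copy())
        return ForwardOutput(conv(self.density), conv(self.raw_density),
                             conv(self.attention), conv(self.probability))

    def density_map(self, index: int = 0) -> DensityMap:
        return DensityMap(values=np.maximum(self.density.data[index, 0], 0.0),
                          origin="prediction")


def build_backbone(spec: NetworkSpec, rng: np.random.Generator | None = None) -> nn.Sequential:
    """First ten VGG-16 convolutions (ReLU after each, three 2x2 max-pools)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    layers: list[nn.Module] = []
    c_in = spec.input_channels
    for item in BACKBONE_PLAN:
        if item == "M":
            layers.append(nn.MaxPool2())
            continue
        c_out = spec.scale(item)
        layers.append(nn.Conv2d(c_in, c_out, kernel=3, dilation=1, rng=rng))
        layers.append(nn.ReLU())
        c_in = c_out
    backbone = nn.Sequential(*layers)
    if spec.pretrained_backbone:
        load_backbone_weights(backbone, spec.pretrained_backbone)
    return backbone


def load_backbone_weights(backbone: nn.Sequential, path: str) -> None:
    """Load VGG-prefix weights from an .npz archive (keys w0,b0,w1,b1,...)."""
    arrays = np.load(path)
    convs = [l for l in backbone.layers if isinstance(l, nn.Conv2d)]
    for i, conv in enumerate(convs):
        w, b = arrays[f"w{i}"], arrays[f"b{i}"]
        if w.shape != conv.weight.data.shape:
            raise ValueError(
                f"pretrained weight {i} has shape {w.shape}, "
                f"expected {conv.weight.data.shape}"
            )
        conv.weight.data = w.astype(np.float32)
        conv.bias.data = b.astype(np.float32)


def build_regression_head(spec: NetworkSpec, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Dilated 3x3 stack (512/512/256/128 scaled) + 1x1 to one channel.

    The raw 1x1 output O_d is unconstrained in sign (clamping it would kill
    gradients early in training); density maps are clamped at zero only when
    read out as a DensityMap. The final 1x1 layer is zero-initialized so that
    optimization starts from the empty density map and grows mass toward the
    labels — label densities are tiny (1/window area per cell) and a
    generically initialized head starts orders of magnitude too large.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    layers: list[nn.Module] = []
    c_in = spec.scale(512)
    for c in HEAD_CHANNELS:
        c_out = spec.scale(c)
        layers.append(nn.Conv2d(c_in, c_out, kernel=3, dilation=spec.dilation_rate, rng=rng))
        layers.append(nn.ReLU())
        c_in = c_out
    final = nn.Conv2d(c_in, 1, kernel=1, rng=rng)
    final.weight.data[:] = 0.0
    layers.append(final)
    return nn.Sequential(*layers)


class _FEMPath(nn.Module):
    """3x3 conv + ReLU, 1x1 conv to one channel, sigmoid.

    The attention path starts as an *open* gate (zero projection weights,
    positive bias, so f is approximately 0.9 everywhere): a randomly
    initialized multiplicative gate can collapse to f = 0 early in training,
    which silences the density head's gradient permanently.
    """

    def __init__(self, c_in: int, rng: np.random.Generator,
                 gate_open_bias: float | None = None):
        self.conv = nn.Conv2d(c_in, c_in, kernel=3, dilation=1, rng=rng)
        self.proj = nn.Conv2d(c_in, 1, kernel=1, rng=rng)
        if gate_open_bias is not None:
            self.proj.weight.data[:] = 0.0
            self.proj.bias.data[:] = gate_open_bias

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(self.conv(x).relu()).sigmoid()

    def describe(self) -> str:
        return f"{self.conv.describe()} -> relu -> {self.proj.describe()} -> sigmoid"


class FEM(nn.Module):
    """Dual-path feature enhancement module off a shared dilated convolution."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator | None = None):
        if spec.variant == "baseline1":
            raise ValueError("baseline1 has no feature enhancement module")
        rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
        c = spec.scale(512)
        self.shared = nn.Conv2d(c, c, kernel=3, dilation=spec.dilation_rate, rng=rng)
        self.attention_path = (_FEMPath(c, rng, gate_open_bias=2.0)
                               if spec.has_attention else None)
        self.supervised_path = _FEMPath(c, rng) if spec.has_supervised else None

    def forward(self, features: Tensor) -> tuple[Tensor | None, Tensor | None]:
        shared = self.shared(features).relu()
        att = self.attention_path(shared) if self.attention_path else None
        prob = self.supervised_path(shared) if self.supervised_path else None
        return att, prob

    def describe(self) -> str:
        parts = [f"shared {self.shared.describe()} -> relu"]
        if self.attention_path:
            parts.append(f"attention: {self.attention_path.describe()}")
        if self.supervised_path:
            parts.append(f"supervised: {self.supervised_path.describe()}")
        return "; ".join(parts)


def build_fem(spec: NetworkSpec, rng: np.random.Generator | None = None) -> FEM:
    return FEM(spec, rng)


class FEGNet(nn.Module):
    """Backbone + regression head + (variant-dependent) FEM."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.backbone = build_backbone(spec, rng)
        self.head = build_regression_head(spec, rng)
        self.fem = build_fem(spec, rng) if spec.variant != "baseline1" else None

    # -- input handling -------------------------------------------------------
    @staticmethod
    def prepare(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        """HWC float image in [0,1] -> padded NCHW batch; returns orig dims."""
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        h, w = image.shape[:2]
        ph, pw = (-h) % 8, (-w) % 8
        if ph or pw:
            image = np.pad(image, ((0, ph), (0, pw), (0, 0)))
        batch = image.transpose(2, 0, 1)[None].astype(np.float32)
        return batch, (h, w)

    @staticmethod
    def normalize(batch: np.ndarray) -> np.ndarray:
        """Min-max normalization to [0,1] per image (non-pretrained mode)."""
        out = batch.astype(np.float32).copy()
        for i in range(out.shape[0]):
            lo, hi = out[i].min(), out[i].max()
            if hi > lo:
                out[i] = (out[i] - lo) / (hi - lo)
        return out

    # -- forward --------------------------------------------------------------
    def forward(self, batch) -> ForwardOutput:
        """Run the network on an NCHW tensor with dims divisible by 8."""
        x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch, dtype=np.float32))
        if x.data.shape[2] % 8 or x.data.shape[3] % 8:
            raise ValueError("input spatial dims must be divisible by 8 (pad first)")
        features = self.backbone(x)
        raw = self.head(features)  # O_d at 1/8 resolution
        attention = probability = None
        if self.fem is not None:
            attention, probability = self.fem(features)
        gated = raw * attention if attention is not None else raw
        density = ag.upsample_bilinear(gated, 8)
        if not np.isfinite(density.data).all():
            raise FloatingPointError("non-finite activations in the density output")
        return ForwardOutput(density=density, raw_density=raw,
                             attention=attention, probability=probability)

    def predict_density(self, image: np.ndarray) -> DensityMap:
        """Full pipeline for one HWC image: pad, normalize, forward, crop."""
        batch, (h, w) = self.prepare(image)
        out = self.forward(self.normalize(batch))
        return DensityMap(values=np.maximum(out.density.data[0, 0, :h, :w], 0.0),
                          origin="prediction")

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.named_parameters()}
        arrays["__spec__"] = np.frombuffer(
            json.dumps(asdict(self.spec)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FEGNet":
        arch = np.load(path)
        spec = NetworkSpec(**json.loads(arch["__spec__"].tobytes().decode()))
        model = cls(spec)
        for name, p in model.named_parameters():
            if name not in arch:
                raise ValueError(f"checkpoint missing parameter {name!r}")
            stored = arch[name]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter {name!r} has shape {stored.shape}, "
                    f"expected {p.data.shape}"
                )
            p.data = stored.astype(np.float32)
        return model

    def summary(self) -> str:
        lines = [f"FEGNet variant={self.spec.variant} width={self.spec.width_multiplier}",
                 f"backbone: {self.backbone.describe()}",
                 f"head: {self.head.describe()}"]
        if self.fem is not None:
            lines.append(f"fem: {self.fem.describe()}")
        lines.append(f"parameters: {self.n_parameters():,}")
        return "\n".join(lines)


def count_from_density(density: DensityMap) -> float:
    """Predicted object count = integral (sum) of the density map."""
    return float(density.values.sum())
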