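"""Training objectives: SSIM density loss, BCE mask loss, and ablation losses.

The density branch is trained with a structural-similarity (SSIM) loss:
``1 - mean(L * C * S)`` over sliding windows, where L, C and S compare local
luminance (means), contrast (standard deviations) and structure (covariance)
between the predicted and ground-truth density maps. SSIM emphasizes the
*shape* of the density surface over raw pixel differences, which suits blob
labels whose exact per-pixel values are tiny.

Stabilizing constants follow the usual convention: c1 = (0.01 R)^2,
c2 = (0.03 R)^2, c3 = c2 / 2 with R the data range. Under c3 = c2/2 the
product C*S collapses to (2*sigma_xy + c2) / (sigma_x^2 + sigma_y^2 + c2),
which is the numerically safe path (no square roots of near-zero variances);
other c3 values use the explicit three-factor form. The contrast denominator
uses sigma_x^2 + sigma_y^2 + c2: this is the form under which C = 1 for
identical inputs, a property the loss relies on (perfect prediction -> 0).

The supervised FEM path is trained with pixel-wise binary cross-entropy
against the pooled foreground mask. The total objective is a weighted sum
of the two (weights default to 1, 1); variants without a supervised path
use the density term alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .labels import ForegroundMask

__all__ = ["SSIMConfig", "LossConfig", "ssim_loss", "bce_loss",
           "alt_density_loss", "total_loss", "density_loss"]

DENSITY_LOSSES = ("ssim", "mse", "l1", "smooth_l1")


@dataclass
class SSIMConfig:
    window_side: int = 11
    window_kind: str = "gaussian"  # gaussian | uniform
    sigma: float = 1.5             # gaussian window only
    c1: float | None = None        # None -> (0.01 * data_range)^2
    c2: float | None = None        # None -> (0.03 * data_range)^2
    c3: float | None = None        # None -> c2 / 2
    data_range: float | str = "auto"  # auto -> max(gt) per batch item

    def __post_init__(self):
        if self.window_side <= 0 or self.window_side % 2 == 0:
            raise ValueError("window_side must be a positive odd integer")
        if self.window_kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown window kind {self.window_kind!r}")
        if isinstance(self.data_range, (int, float)) and self.data_range <= 0:
            raise ValueError("data_range must be positive")


@dataclass
class LossConfig:
    density_loss: str = "ssim"
    ssim: SSIMConfig = field(default_factory=SSIMConfig)
    mask_threshold: float = 0.0
    loss_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.density_loss not in DENSITY_LOSSES:
            raise ValueError(f"density_loss must be one of {DENSITY_LOSSES}")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")


def _as_nchw(x) -> Tensor:
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))  # Tensor promotes non-float to float32
    if x.data.ndim == 2:
        x = x.reshape(1, 1, *x.data.shape)
    elif x.data.ndim == 3:
        x = x.reshape(x.data.shape[0], 1, *x.data.shape[1:])
    return x


def _ssim_window(cfg: SSIMConfig) -> Tensor:
    k = cfg.window_side
    if cfg.window_kind == "uniform":
        w = np.full((k, k), 1.0 / (k * k))
    else:
        ax = np.arange(k) - k // 2
        g = np.exp(-(ax ** 2) / (2.0 * cfg.sigma ** 2))
        w = np.outer(g, g)
        w /= w.sum()
    return Tensor(w.reshape(1, 1, k, k))


def _resolve_constants(cfg: SSIMConfig, gt: np.ndarray):
    n = gt.shape[0]
    if cfg.data_range == "auto":
        dr = np.maximum(gt.reshape(n, -1).max(axis=1), 1e-12)
    else:
        dr = np.full(n, float(cfg.data_range))
    dr = dr.reshape(n, 1, 1, 1).astype(gt.dtype if np.issubdtype(gt.dtype, np.floating) else np.float32)
    c1 = np.full_like(dr, cfg.c1) if cfg.c1 is not None else (0.01 * dr) ** 2
    c2 = np.full_like(dr, cfg.c2) if cfg.c2 is not None else (0.03 * dr) ** 2
    c3 = np.full_like(dr, cfg.c3) if cfg.c3 is not None else c2 / 2.0
    return c1, c2, c3


def ssim_map(pred: Tensor, gt: Tensor, cfg: SSIMConfig) -> Tensor:
    """Per-position SSIM between two NCHW maps (reflection-padded borders)."""
    window = _ssim_window(cfg)
    pad = cfg.window_side // 2

    def local_mean(t: Tensor) -> Tensor:
        return ag.conv2d(ag.reflect_pad2d(t, pad), window)

    mu_x = local_mean(pred)
    mu_y = local_mean(gt)
    # local second moments; variances clamped at zero against roundoff
    var_x = (local_mean(pred * pred) - mu_x * mu_x).relu()
    var_y = (local_mean(gt * gt) - mu_y * mu_y).relu()
    cov = local_mean(pred * gt) - mu_x * mu_y

    c1a, c2a, c3a = _resolve_constants(cfg, gt.data)
    c1, c2, c3 = Tensor(c1a), Tensor(c2a), Tensor(c3a)

    lum = (2.0 * mu_x * mu_y + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
    if np.allclose(c3a, c2a / 2.0):
        cs = (2.0 * cov + c2) / (var_x + var_y + c2)
        return lum * cs
    sd_x = (var_x + 1e-24).sqrt()
    sd_y = (var_y + 1e-24).sqrt()
    contrast = (2.0 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    structure = (cov + c3) / (sd_x * sd_y + c3)
    return lum * contrast * structure


def ssim_loss(pred, gt, cfg: SSIMConfig | None = None) -> Tensor:
    """``1 - mean(SSIM)``; 0 for identical maps, at most 2."""
    cfg = cfg or SSIMConfig()
    pred, gt = _as_nchw(pred), _as_nchw(gt)
    if pred.data.shape != gt.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {gt.data.shape}")
    return 1.0 - ssim_map(pred, gt, cfg).mean()


def bce_loss(probability, mask) -> Tensor:
    """Pixel-mean binary cross-entropy with clamped probabilities."""
    p = _as_nchw(probability)
    y = mask.values if isinstance(mask, ForegroundMask) else np.asarray(mask)
    y = _as_nchw(y.astype(np.float32))
    if p.data.shape != y.data.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {y.data.shape}")
    p = p.clip(1e-7, 1.0 - 1e-7)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def alt_density_loss(pred, gt, kind: str) -> Tensor:
    """Pixel-averaged L1 / MSE / smooth-L1 alternatives to the SSIM loss."""
    pred, gt = _as_nchw(pred), _as_nchw(gt)
    if pred.data.shape != gt.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {gt.data.shape}")
    d = pred - gt
    if kind == "l1":
        return (d.relu() + (-d).relu()).mean()
    if kind == "mse":
        return (d * d).mean()
    if kind == "smooth_l1":
        absd = d.relu() + (-d).relu()
        quad = (np.abs(d.data) < 1.0).astype(np.float32)  # branch select, no grad
        sel = Tensor(quad)
        return (sel * (0.5 * d * d) + (1.0 - sel) * (absd - 0.5)).mean()
    raise ValueError(f"unknown density loss kind {kind!r}")


def density_loss(pred, gt, cfg: LossConfig) -> Tensor:
    if cfg.density_loss == "ssim":
        return ssim_loss(pred, gt, cfg.ssim)
    return alt_density_loss(pred, gt, cfg.density_loss)


def total_loss(out, gt_density, gt_mask, cfg: LossConfig) -> tuple[Tensor, dict]:
    """Weighted sum of the density loss and (if present) the mask BCE.

    ``out`` is a ForwardOutput; variants without a supervised path return the
    density term alone. Returns (scalar tensor, float components dict).
    """
    w1, w2 = cfg.loss_weights
    dl = density_loss(out.density, gt_density, cfg)
    components = {"density": float(dl.data)}
    if out.probability is None:
        total = w1 * dl
        components["mask"] = 0.0
    else:
        if gt_mask is None:
            raise ValueError("supervised variant needs a foreground mask")
        ml = bce_loss(out.probability, gt_mask)
        components["mask"] = float(ml.data)
        total = w1 * dl + w2 * ml
    components["total"] = float(total.data)
    return total, components
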