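"""Data pipeline, augmentation and the seeded training loop.

Augmentations mirror field practice for counting networks: random square
crop, random horizontal flip, random gamma (illumination) transform and
random grayscale conversion. Point annotations are transformed alongside the
image and density labels are regenerated *after* augmentation from the
transformed points, so label mass exactly equals the surviving point count
under any crop.

Training minimizes the combined objective (density loss + mask BCE) with
Adam at a constant learning rate; the checkpoint with the lowest validation
MAE is retained. All randomness flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor
from .labels import (KernelSpec, PointSet, binarize_density, downsample_mask,
                     generate_density, pad_mask_divisible)
from .losses import LossConfig, total_loss
from .network import FEGNet, NetworkSpec

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 600
    batch_size: int = 8
    learning_rate: float = 1e-5
    optimizer: str = "adam"
    seed: int = 0
    crop_fraction: float = 0.5
    flip_prob: float = 0.5
    gamma_prob: float = 0.3
    gamma_range: tuple[float, float] = (0.5, 1.5)
    grayscale_prob: float = 0.1
    val_every: int = 1

    def __post_init__(self):
        for name in ("flip_prob", "gamma_prob", "grayscale_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.crop_fraction <= 1:
            raise ValueError("crop_fraction must lie in (0, 1]")
        lo, hi = self.gamma_range
        if not (0 < lo < hi):
            raise ValueError("gamma_range must satisfy 0 < lo < hi")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class SplitSpec:
    train_n: int
    val_n: int
    test_n: int | None = None  # None -> remainder
    seed: int = 0


def make_split(n: int, spec: SplitSpec) -> dict[str, np.ndarray]:
    """Deterministic shuffle of ``range(n)`` into train/val/test indices."""
    if spec.train_n + spec.val_n > n:
        raise ValueError(
            f"split oversubscribed: train {spec.train_n} + val {spec.val_n} > n {n}"
        )
    order = np.random.default_rng(spec.seed).permutation(n)
    t, v = spec.train_n, spec.val_n
    test = order[t + v:]
    if spec.test_n is not None:
        if t + v + spec.test_n > n:
            raise ValueError("split oversubscribed")
        test = test[:spec.test_n]
    return {"train": order[:t], "val": order[t:t + v], "test": test}


def apply_crop(image: np.ndarray, pts: list[tuple[float, float]],
               x0: int, y0: int, side: int):
    """Crop a square window; points outside are dropped, the rest shifted."""
    img = image[y0:y0 + side, x0:x0 + side]
    kept = [(x - x0, y - y0) for x, y in pts
            if x0 <= x < x0 + side and y0 <= y < y0 + side]
    return img, kept


def augment(image: np.ndarray, points: PointSet, cfg: TrainConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, PointSet]:
    """Random crop / flip / gamma / grayscale on an (image, points) pair."""
    h, w = image.shape[:2]
    img = image
    pts = list(points.points)

    if cfg.crop_fraction < 1.0:
        side = int(round(cfg.crop_fraction * min(h, w)))
        side -= side % 8  # keep network-compatible dims
        if side < 8:
            raise ValueError("crop smaller than 8 px")
        y0 = int(rng.integers(0, h - side + 1))
        x0 = int(rng.integers(0, w - side + 1))
        img, pts = apply_crop(img, pts, x0, y0, side)
        h = w = side

    if rng.random() < cfg.flip_prob:
        img = img[:, ::-1]
        # w-1-x maps pixel centers exactly; continuous x in (w-1, w) would
        # land just below 0, so clamp into bounds
        pts = [(min(max(w - 1 - x, 0.0), w - 1.0), y) for x, y in pts]

    if rng.random() < cfg.gamma_prob:
        gamma = rng.uniform(*cfg.gamma_range)
        img = np.clip(img, 0.0, 1.0) ** gamma

    if rng.random() < cfg.grayscale_prob:
        gray = img @ np.array([0.299, 0.587, 0.114], dtype=img.dtype)
        img = np.stack([gray] * 3, axis=-1)

    out_points = PointSet(image_id=points.image_id, width=w, height=h,
                          points=pts)
    return np.ascontiguousarray(img), out_points


def _pad8(arr: np.ndarray) -> np.ndarray:
    """Zero-pad the two leading (spatial) axes up to multiples of 8."""
    h, w = arr.shape[:2]
    ph, pw = (-h) % 8, (-w) % 8
    if ph == 0 and pw == 0:
        return arr
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad)


def _labels_for(points: PointSet, kernel: KernelSpec, mask_threshold: float):
    density = generate_density(points, kernel)
    mask = pad_mask_divisible(binarize_density(density, mask_threshold))
    return _pad8(density.values), downsample_mask(mask).values


def evaluate_counts(model: FEGNet, dataset) -> list[tuple[str, int, float]]:
    """(image_id, true count, predicted count) on full images, batch 1."""
    rows = []
    for image, points in dataset:
        pred = model.predict_density(image)
        rows.append((points.image_id, points.count, float(pred.values.sum())))
    return rows


def _mae_rmse(rows) -> tuple[float, float]:
    err = np.array([z - zh for _, z, zh in rows], dtype=np.float64)
    return float(np.abs(err).mean()), float(np.sqrt((err ** 2).mean()))


def train(model_spec: NetworkSpec, loss_cfg: LossConfig, train_cfg: TrainConfig,
          dataset, val_dataset=None, kernel: KernelSpec | None = None,
          out_dir=None) -> tuple[FEGNet, list[dict]]:
    """Train FEG Net; returns (best model by validation MAE, history).

    ``dataset``/``val_dataset`` are sequences of (HWC image in [0,1],
    PointSet). Without a validation set the final model is returned.
    """
    kernel = kernel or KernelSpec()
    rng = np.random.default_rng(train_cfg.seed)
    model = FEGNet(model_spec)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)

    history: list[dict] = []
    best_mae = math.inf
    best_state = {name: p.data.copy() for name, p in model.named_parameters()}

    n = len(dataset)
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            batch_idx = order[start:start + train_cfg.batch_size]
            images, densities, masks = [], [], []
            for i in batch_idx:
                image, points = dataset[int(i)]
                img, pts = augment(image, points, train_cfg, rng)
                d, m = _labels_for(pts, kernel, loss_cfg.mask_threshold)
                images.append(_pad8(img).transpose(2, 0, 1))
                densities.append(d[None])
                masks.append(m[None])
            batch = FEGNet.normalize(np.stack(images))
            out = model.forward(Tensor(batch))
            gt_density = np.stack(densities).astype(np.float32)
            gt_mask = np.stack(masks).astype(np.float32) if out.probability is not None else None
            loss, comps = total_loss(out, gt_density, gt_mask, loss_cfg)
            if not math.isfinite(comps["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(comps["total"])

        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_dataset is not None and epoch % train_cfg.val_every == 0:
            rows = evaluate_counts(model, val_dataset)
            record["val_mae"], record["val_rmse"] = _mae_rmse(rows)
            if record["val_mae"] < best_mae:
                best_mae = record["val_mae"]
                best_state = {name: p.data.copy()
                              for name, p in model.named_parameters()}
        history.append(record)
        logger.info("epoch %d: %s", epoch, record)

    if val_dataset is not None:
        for name, p in model.named_parameters():
            p.data = best_state[name]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "best.npz")
        fields_ = sorted({k for r in history for k in r})
        with open(out / "history.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=fields_)
            writer.writeheader()
            writer.writerows(history)
        import json

        (out / "config.json").write_text(json.dumps(
            {"network": asdict(model_spec),
             "train": asdict(train_cfg),
             "kernel": asdict(kernel)}, indent=1, default=str))
    return model, history


def train_steps_single_batch(model: FEGNet, loss_cfg: LossConfig,
                             batch: np.ndarray, gt_density: np.ndarray,
                             gt_mask: np.ndarray | None, steps: int,
                             lr: float) -> list[float]:
    """Repeated Adam steps on one fixed batch; returns the loss trace."""
    opt = nn.Adam(model.parameters(), lr=lr)
    trace = []
    for _ in range(steps):
        out = model.forward(Tensor(batch))
        mask = gt_mask if out.probability is not None else None
        loss, comps = total_loss(out, gt_density, mask, loss_cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(comps["total"])
    return trace
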