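"""Point annotations and their conversion to density-map training labels.

Fruit positions are annotated as a single point per object (Labelme JSON,
shape_type ``point``). Each point is converted into a small patch of density
that integrates to one, so the integral of the full map equals the object
count. Two kernels are supported:

* ``uniform`` — the point's unit mass is spread evenly over an axis-aligned
  square window of side ``window_side`` centered on the rounded point. This
  matches near-spherical fruit whose surface appearance is roughly uniform.
* ``gaussian`` — the classical crowd-counting alternative: a normalized
  discrete Gaussian of standard deviation ``sigma`` on the same window.

Coordinates are 0-based with x = column, y = row; pixel centers sit at
integer coordinates. Window centers use half-up rounding of the continuous
annotation coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "PointSet",
    "KernelSpec",
    "DensityMap",
    "ForegroundMask",
    "parse_labelme",
    "generate_density",
    "binarize_density",
    "downsample_mask",
    "pad_mask_divisible",
    "save_density_h5",
    "load_density_h5",
]


@dataclass
class PointSet:
    """Per-image fruit-center annotations in pixel coordinates."""

    image_id: str
    width: int
    height: int
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        for i, (x, y) in enumerate(self.points):
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(
                    f"point {i} at ({x}, {y}) outside {self.width}x{self.height} image"
                )

    @property
    def count(self) -> int:
        return len(self.points)


@dataclass
class KernelSpec:
    """How a single point spreads its unit mass into the density map."""

    kind: str = "uniform"  # uniform | gaussian
    window_side: int = 15
    sigma: float = 4.0
    border_policy: str = "renormalize"  # renormalize | truncate

    def __post_init__(self):
        if self.kind not in ("uniform", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.window_side <= 0 or self.window_side % 2 == 0:
            raise ValueError("window_side must be a positive odd integer")
        if self.kind == "gaussian" and not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and positive")
        if self.border_policy not in ("renormalize", "truncate"):
            raise ValueError(f"unknown border policy {self.border_policy!r}")


@dataclass
class DensityMap:
    """Non-negative grid whose integral encodes the object count."""

    values: np.ndarray  # (height, width) float
    origin: str = "label"  # label | prediction

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")

    @property
    def count(self) -> float:
        return float(self.values.sum())


@dataclass
class ForegroundMask:
    """Binary grid marking where label density is present."""

    values: np.ndarray
    scale: str = "full"  # full | eighth

    def __post_init__(self):
        self.values = np.asarray(self.values)
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.values = self.values.astype(np.uint8)


def parse_labelme(json_text: str) -> PointSet:
    """Parse a Labelme annotation document into a :class:`PointSet`.

    Only shapes of type ``point`` are considered; each contributes exactly
    one (x, y) pair, order preserved. Points outside the image raise a
    ``ValueError`` naming the offending index.
    """
    doc = json.loads(json_text)
    try:
        width = int(doc["imageWidth"])
        height = int(doc["imageHeight"])
    except KeyError as exc:
        raise ValueError(f"Labelme JSON missing field {exc}") from exc
    image_id = str(doc.get("imagePath", "image")).rsplit(".", 1)[0]
    points = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type") != "point":
            continue
        (x, y), = shape["points"]
        points.append((float(x), float(y)))
    return PointSet(image_id=image_id, width=width, height=height, points=points)


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def generate_density(points: PointSet, spec: KernelSpec | None = None) -> DensityMap:
    """Convert point annotations into a density map (sum of per-point kernels).

    With ``border_policy='renormalize'`` each point integrates to exactly 1
    even when its window is clipped at the image border, so the map total
    equals the point count. With ``'truncate'`` the clipped mass is lost.
    """
    spec = spec or KernelSpec()
    h, w = points.height, points.width
    if h <= 0 or w <= 0:
        raise ValueError("zero-size image")
    if spec.border_policy == "truncate" and spec.window_side >= min(h, w):
        import logging

        logging.getLogger(__name__).warning(
            "window_side %d >= min image dim %d with truncate policy: "
            "points near borders will lose most of their mass",
            spec.window_side, min(h, w),
        )
    density = np.zeros((h, w), dtype=np.float64)
    half = spec.window_side // 2

    if spec.kind == "gaussian":
        ax = np.arange(spec.window_side) - half
        gx = np.exp(-(ax ** 2) / (2.0 * spec.sigma ** 2))
        kernel = np.outer(gx, gx)
        kernel /= kernel.sum()
    else:
        kernel = np.full((spec.window_side, spec.window_side),
                         1.0 / spec.window_side ** 2)

    for x, y in points.points:
        cx, cy = _round_half_up(x), _round_half_up(y)
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        kr0, kc0 = max(0, -r0), max(0, -c0)
        r0c, c0c = max(0, r0), max(0, c0)
        r1c, c1c = min(h, r1), min(w, c1)
        patch = kernel[kr0:kr0 + (r1c - r0c), kc0:kc0 + (c1c - c0c)]
        if spec.border_policy == "renormalize":
            mass = patch.sum()
            if mass <= 0:
                raise ValueError("kernel window entirely outside the image")
            patch = patch / mass
        density[r0c:r1c, c0c:c1c] += patch
    return DensityMap(values=density, origin="label")


def binarize_density(density: DensityMap, threshold: float = 0.0) -> ForegroundMask:
    """Foreground mask: 1 where density strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return ForegroundMask(values=(density.values > threshold).astype(np.uint8),
                          scale="full")


def pad_mask_divisible(mask: ForegroundMask, factor: int = 8) -> ForegroundMask:
    """Zero-pad right/bottom so both dims divide ``factor``."""
    h, w = mask.values.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph == 0 and pw == 0:
        return mask
    return ForegroundMask(values=np.pad(mask.values, ((0, ph), (0, pw))),
                          scale=mask.scale)


def downsample_mask(mask: ForegroundMask, factor: int = 8) -> ForegroundMask:
    """Max-pool a full-resolution mask to the network's 1/8 feature grid."""
    if mask.scale != "full":
        raise ValueError("expected a full-resolution mask")
    h, w = mask.values.shape
    if h % factor or w % factor:
        raise ValueError(
            f"mask dims {h}x{w} not divisible by {factor}; pad first "
            "(see pad_mask_divisible)"
        )
    blocks = mask.values.reshape(h // factor, factor, w // factor, factor)
    return ForegroundMask(values=blocks.max(axis=(1, 3)), scale="eighth")


def save_density_h5(path, maps: Iterable[tuple[str, DensityMap]]) -> None:
    """Persist density maps as float32 HDF5 datasets keyed by image id."""
    import h5py

    with h5py.File(path, "w") as f:
        for image_id, dmap in maps:
            f.create_dataset(image_id, data=dmap.values.astype(np.float32))


def load_density_h5(path) -> dict[str, DensityMap]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for key in f:
            out[key] = DensityMap(values=f[key][()], origin="label")
    return out
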