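"""Seeded synthetic orchard scenes with exact point ground truth.

Real high-density fruit photos pose four difficulties: heavy occlusion,
large scale variation, illumination changes and cluttered backgrounds. The
generator reproduces controlled versions of all four: fruit are shaded
reddish ellipses of randomized radius placed by rejection sampling with a
bounded pairwise-occlusion fraction, over a textured green-brown background
with non-fruit distractor ellipses; a global gamma draw varies illumination.
Every rendered fruit contributes its exact center to the PointSet, including
partially occluded ones.

Scenes fall into the four density classes used to stratify the real data:
low (1-50 objects), medium (51-100), high (101-200) and ultra (>200, capped).
Everything is a pure function of the seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labels import PointSet

logger = logging.getLogger(__name__)

DENSITY_CLASSES = {
    "low": (1, 50),
    "medium": (51, 100),
    "high": (101, 200),
    "ultra": (201, None),  # upper bound = SceneSpec.ultra_cap
}


@dataclass
class SceneSpec:
    width: int = 256
    height: int = 256
    density_class: str | None = "low"
    count: int | None = None          # explicit count overrides the class
    radius_range: tuple[float, float] = (3.0, 8.0)
    max_overlap: float = 0.3          # allowed occluded fraction of a new blob
    hue_jitter: float = 0.08
    gamma_range: tuple[float, float] = (0.7, 1.4)
    clutter_level: float = 0.3
    ultra_cap: int = 300
    seed: int = 0

    def __post_init__(self):
        r0, r1 = self.radius_range
        if not (0 < r0 <= r1):
            raise ValueError("need 0 < r_min <= r_max")
        if not (0 <= self.max_overlap < 1):
            raise ValueError("max_overlap must lie in [0, 1)")
        if self.count is None and self.density_class not in DENSITY_CLASSES:
            raise ValueError(f"unknown density class {self.density_class!r}")

    def sample_count(self, rng: np.random.Generator) -> int:
        if self.count is not None:
            return int(self.count)
        lo, hi = DENSITY_CLASSES[self.density_class]
        hi = hi if hi is not None else self.ultra_cap
        return int(rng.integers(lo, hi + 1))


def _circle_overlap_fraction(c1, r1, c2, r2) -> float:
    """Fraction of circle 1's area covered by circle 2 (lens formula)."""
    d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        inter = np.pi * min(r1, r2) ** 2
    else:
        a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        a3 = 0.5 * np.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2)
                               * (d - r1 + r2) * (d + r1 + r2)))
        inter = a1 + a2 - a3
    return float(inter / (np.pi * r1 * r1))


def _smooth_noise(rng: np.random.Generator, h: int, w: int, cell: int = 16) -> np.ndarray:
    """Low-frequency scalar field in [-1, 1] from an upsampled coarse grid."""
    gh, gw = max(2, h // cell + 2), max(2, w // cell + 2)
    grid = rng.uniform(-1, 1, size=(gh, gw))
    ys = np.linspace(0, gh - 1.001, h)
    xs = np.linspace(0, gw - 1.001, w)
    y0 = ys.astype(int)
    x0 = xs.astype(int)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    g = (grid[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
         + grid[np.ix_(y0 + 1, x0)] * fy * (1 - fx)
         + grid[np.ix_(y0, x0 + 1)] * (1 - fy) * fx
         + grid[np.ix_(y0 + 1, x0 + 1)] * fy * fx)
    return g


def _draw_ellipse(img: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                  color: np.ndarray, shade: float = 0.6) -> None:
    """Opaque radially-shaded ellipse, painted in place."""
    h, w = img.shape[:2]
    x0, x1 = max(0, int(cx - rx - 1)), min(w, int(cx + rx + 2))
    y0, y1 = max(0, int(cy - ry - 1)), min(h, int(cy + ry + 2))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    inside = d2 <= 1.0
    if not inside.any():
        return
    shading = 1.0 - shade * d2[inside]
    # small top-left highlight for a convex-fruit look
    hl = np.exp(-(((xx - cx + 0.35 * rx) / rx) ** 2
                  + ((yy - cy + 0.35 * ry) / ry) ** 2) * 4.0)[inside]
    patch = color[None, :] * shading[:, None] + 0.25 * hl[:, None]
    img[yy[inside], xx[inside]] = np.clip(patch, 0.0, 1.0)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, PointSet]:
    """Render one scene; returns (HWC float image in [0,1], PointSet)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n_target = spec.sample_count(rng)

    # textured green-brown background
    base = np.array([0.16, 0.30, 0.10]) + rng.uniform(-0.04, 0.04, 3)
    img = np.clip(
        base[None, None, :]
        + 0.10 * _smooth_noise(rng, h, w, cell=12)[:, :, None]
        + 0.05 * rng.standard_normal((h, w, 3)),
        0.0, 1.0,
    )

    # clutter: leaves / branches — greens, browns, yellows (never reddish)
    n_clutter = int(round(spec.clutter_level * 40))
    clutter_colors = np.array([
        [0.25, 0.45, 0.12],   # bright leaf
        [0.35, 0.28, 0.12],   # branch brown
        [0.55, 0.55, 0.15],   # dry leaf yellow
        [0.10, 0.22, 0.08],   # dark foliage
    ])
    for _ in range(n_clutter):
        color = clutter_colors[rng.integers(len(clutter_colors))] \
            * rng.uniform(0.8, 1.2)
        _draw_ellipse(
            img, rng.uniform(0, w), rng.uniform(0, h),
            rng.uniform(2, 14), rng.uniform(2, 14),
            np.clip(color, 0, 1), shade=0.3,
        )

    # fruit placement by rejection with bounded pairwise occlusion
    placed: list[tuple[float, float, float]] = []  # (cx, cy, r)
    max_tries = 200
    for _ in range(n_target):
        r = rng.uniform(*spec.radius_range)
        ok = False
        for _try in range(max_tries):
            cx = rng.uniform(r * 0.5, w - 1 - r * 0.5)
            cy = rng.uniform(r * 0.5, h - 1 - r * 0.5)
            if all(_circle_overlap_fraction((cx, cy), r, (px, py), pr)
                   <= spec.max_overlap for px, py, pr in placed):
                ok = True
                break
        if not ok:
            logger.warning(
                "placement failed after %d tries; rendering %d of %d fruit",
                max_tries, len(placed), n_target,
            )
            break
        placed.append((cx, cy, r))

    fruit_base = np.array([0.72, 0.16, 0.10])
    points = []
    for cx, cy, r in placed:
        color = np.clip(fruit_base + rng.uniform(-spec.hue_jitter,
                                                 spec.hue_jitter, 3), 0, 1)
        ry = r * rng.uniform(0.85, 1.1)
        _draw_ellipse(img, cx, cy, r, ry, color, shade=0.6)
        points.append((float(cx), float(cy)))

    gamma = rng.uniform(*spec.gamma_range)
    img = np.clip(img, 0.0, 1.0) ** gamma

    pset = PointSet(image_id=f"scene_{spec.seed}", width=w, height=h,
                    points=points)
    return img.astype(np.float32), pset


def to_labelme_json(pset: PointSet, image_path: str) -> str:
    doc = {
        "version": "5.1.1",
        "flags": {},
        "shapes": [
            {
                "label": "fruit",
                "points": [[x, y]],
                "group_id": None,
                "shape_type": "point",
                "flags": {},
            }
            for x, y in pset.points
        ],
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": pset.height,
        "imageWidth": pset.width,
    }
    return json.dumps(doc, indent=1)


def generate_dataset(n_per_class: dict[str, int], out_dir, seed: int = 0,
                     size: int = 256, **scene_kwargs) -> list[dict]:
    """Write PNG images + Labelme JSON + a manifest CSV; returns the manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    manifest = []
    idx = 0
    for cls in ("low", "medium", "high", "ultra"):
        for _ in range(int(n_per_class.get(cls, 0))):
            child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            spec = SceneSpec(width=size, height=size, density_class=cls,
                             seed=child_seed, **scene_kwargs)
            img, pset = generate_scene(spec)
            image_id = f"img_{idx:05d}"
            pset.image_id = image_id
            iio.imwrite(out / f"{image_id}.png",
                        (img * 255).round().astype(np.uint8))
            (out / f"{image_id}.json").write_text(
                to_labelme_json(pset, f"{image_id}.png"))
            manifest.append({"image_id": image_id, "class": cls,
                             "count": pset.count})
            idx += 1
    with open(out / "manifest.csv", "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=["image_id", "class", "count"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest


def scene_batch(n: int, classes: tuple[str, ...] = ("low", "medium"),
                size: int = 128, seed: int = 0,
                **scene_kwargs) -> list[tuple[np.ndarray, PointSet]]:
    """In-memory dataset: ``n`` scenes cycling through ``classes``."""
    root = np.random.SeedSequence(seed)
    out = []
    for i in range(n):
        child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        spec = SceneSpec(width=size, height=size,
                         density_class=classes[i % len(classes)],
                         seed=child_seed, **scene_kwargs)
        out.append(generate_scene(spec))
    return out
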