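"""Counting metrics, dataset statistics and density-map visualization.

Counting literature reports MAE and an "MSE" column. The MAE is the mean
absolute counting error. The second metric as a formula is the mean of
squared errors, but the values the field tabulates are on the same scale as
MAE — i.e. a root-mean-square error. Both are exposed here: ``mse_printed``
is the literal mean of squares and ``rmse`` its square root; tables should
show ``rmse`` when comparing against published numbers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labels import DensityMap, PointSet
from .network import FEGNet, count_from_density

DENSITY_CLASS_EDGES = ((1, 50), (51, 100), (101, 200))  # 4th class: > 200


@dataclass
class EvalResult:
    per_image: list[tuple[str, int, float]]  # (image_id, Z, Z_hat)
    mae: float
    mse_printed: float  # mean of squared errors, as the formula is written
    rmse: float         # sqrt(mse_printed): the scale the field tabulates

    @property
    def n(self) -> int:
        return len(self.per_image)


def compute_metrics(per_image) -> EvalResult:
    """MAE / mean-of-squares / RMS counting errors from (id, Z, Z_hat) rows."""
    rows = [(str(i), int(z), float(zh)) for i, z, zh in per_image]
    if not rows:
        raise ValueError("need at least one (true, predicted) pair")
    err = np.array([z - zh for _, z, zh in rows], dtype=np.float64)
    mse = float((err ** 2).mean())
    return EvalResult(per_image=rows, mae=float(np.abs(err).mean()),
                      mse_printed=mse, rmse=float(np.sqrt(mse)))


def evaluate_model(model: FEGNet | str, dataset, out_dir=None) -> EvalResult:
    """Forward every image (batch 1, full resolution) and score the counts."""
    if not isinstance(model, FEGNet):
        model = FEGNet.load(model)
    rows = []
    for image, points in dataset:
        density = model.predict_density(image)
        rows.append((points.image_id, points.count, count_from_density(density)))
    result = compute_metrics(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "per_image.csv", "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["image_id", "true_count", "predicted_count", "abs_err"])
            for image_id, z, zh in result.per_image:
                writer.writerow([image_id, z, f"{zh:.3f}", f"{abs(z - zh):.3f}"])
        import json

        (out / "summary.json").write_text(json.dumps(
            {"mae": result.mae, "rmse": result.rmse,
             "mse_printed": result.mse_printed, "n": result.n}, indent=1))
    return result


def relative_improvement(metric_a: float, metric_b: float) -> float:
    """Percent improvement of b over a: 100*(a-b)/a, one decimal."""
    if metric_a <= 0:
        raise ValueError("reference metric must be positive")
    return round(100.0 * (metric_a - metric_b) / metric_a, 1)


def dataset_stats(point_sets) -> dict:
    """Totals, headline mean count, and the four-class density histogram."""
    point_sets = list(point_sets)
    if not point_sets:
        raise ValueError("need at least one PointSet")
    counts = np.array([ps.count for ps in point_sets])
    histogram = {
        "low (1-50)": int(((counts >= 1) & (counts <= 50)).sum()),
        "medium (51-100)": int(((counts >= 51) & (counts <= 100)).sum()),
        "high (101-200)": int(((counts >= 101) & (counts <= 200)).sum()),
        "ultra (>200)": int((counts > 200).sum()),
    }
    return {
        "n_images": len(point_sets),
        "total_annotations": int(counts.sum()),
        "mean_per_image": int(round(counts.mean())) if counts.size else 0,
        "zero_count_images": int((counts == 0).sum()),
        "class_histogram": histogram,
    }


def visualize_density(image: np.ndarray, density: DensityMap, out_path,
                      predicted_count: float | None = None) -> float:
    """Heat-map overlay PNG annotated with the count; returns the count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = density.values
    if image.shape[:2] != values.shape:
        raise ValueError(
            f"image {image.shape[:2]} and density {values.shape} disagree"
        )
    count = (count_from_density(density) if predicted_count is None
             else float(predicted_count))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image)
    ax.imshow(values, cmap="jet", alpha=0.45)
    ax.set_title(f"count = {count:.1f}")
    ax.axis("off")
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return count
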