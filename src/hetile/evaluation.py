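"""Classification metrics and per-slide heterogeneity maps.

Metrics per evaluation set: accuracy, AUC-ROC (rank-based, tie-corrected,
via scikit-learn), F1 for the positive class, the 2x2 confusion matrix at
threshold 0.5, and a normal-approximation 95% confidence interval for
accuracy, p +/- 1.96*sqrt(p(1-p)/n), clipped to [0, 1] (an exact
Clopper-Pearson interval is available behind a flag).

Heterogeneity maps reassemble tile predictions onto the slide's tile grid;
cells with no retained tile (background-discarded or edge-dropped) are
missing and rendered white. Per-slide accuracy is agreement of non-missing
cells with the slide's bulk label — a map-level summary, not tile-level
ground truth, since tile labels are inherited from the slide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import stats
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score

from .classifier import TilePrediction

__all__ = [
    "MetricsReport",
    "HeterogeneityMap",
    "compute_metrics",
    "assemble_map",
    "render_map",
]

MISSING = -1
PALETTE = {1: (247, 214, 26), 0: (38, 70, 183), MISSING: (255, 255, 255)}  # yellow/blue/white


@dataclass
class MetricsReport:
    set_name: str
    n_tiles: int
    accuracy: float
    auc_roc: float          # NaN when truth is single-class
    f1: float
    confusion: np.ndarray   # rows = truth, cols = prediction
    accuracy_ci95: tuple[float, float]


def _accuracy_ci(p: float, n: int, exact: bool = False) -> tuple[float, float]:
    if exact:
        k = int(round(p * n))
        lo = stats.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
        return float(lo), float(hi)
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    return float(max(0.0, p - half)), float(min(1.0, p + half))


def compute_metrics(predictions: list[TilePrediction], set_name: str = "test",
                    exact_ci: bool = False) -> MetricsReport:
    """Score a prediction set; single-class truth gives an undefined (NaN) AUC."""
    if not predictions:
        raise ValueError("no predictions to score")
    truth = np.array([p.truth for p in predictions])
    label_hat = np.array([p.label_hat for p in predictions])
    score = np.array([p.score for p in predictions])
    acc = float(accuracy_score(truth, label_hat))
    f1 = float(f1_score(truth, label_hat, pos_label=1, zero_division=0.0))
    auc = (float(roc_auc_score(truth, score))
           if np.unique(truth).size == 2 else float("nan"))
    conf = confusion_matrix(truth, label_hat, labels=[0, 1])
    return MetricsReport(set_name=set_name, n_tiles=len(predictions),
                         accuracy=acc, auc_roc=auc, f1=f1, confusion=conf,
                         accuracy_ci95=_accuracy_ci(acc, len(predictions), exact_ci))


@dataclass
class HeterogeneityMap:
    slide_id: str
    grid: np.ndarray        # (rows, cols) with entries {0, 1, MISSING}
    bulk_label: int
    per_slide_accuracy: float


def assemble_map(predictions: list[TilePrediction], bulk_label: int) -> HeterogeneityMap:
    """Place one slide's tile predictions on the (row, col) grid."""
    if not predictions:
        raise ValueError("no tiles: cannot assemble a map from an empty slide")
    slide_ids = {p.slide_id for p in predictions}
    if len(slide_ids) != 1:
        raise ValueError(f"predictions span multiple slides: {sorted(slide_ids)}")
    seen = set()
    for p in predictions:
        if (p.row, p.col) in seen:
            raise ValueError(f"duplicate tile position ({p.row}, {p.col}) "
                             f"on slide {p.slide_id}")
        seen.add((p.row, p.col))
    n_rows = max(p.row for p in predictions) + 1
    n_cols = max(p.col for p in predictions) + 1
    grid = np.full((n_rows, n_cols), MISSING, dtype=int)
    for p in predictions:
        grid[p.row, p.col] = p.label_hat
    filled = grid != MISSING
    acc = float((grid[filled] == bulk_label).mean())
    return HeterogeneityMap(slide_id=slide_ids.pop(), grid=grid,
                            bulk_label=bulk_label, per_slide_accuracy=acc)


def render_map(hmap: HeterogeneityMap, path: str | Path, cell_size: int = 16,
               palette: dict[int, tuple[int, int, int]] | None = None) -> Path:
    """Write the map as a PNG: one colored cell per tile, missing cells white."""
    merged = dict(PALETTE)
    merged.update(palette or {})
    palette = merged
    rows, cols = hmap.grid.shape
    img = np.empty((rows, cols, 3), dtype=np.uint8)
    for value, color in palette.items():
        img[hmap.grid == value] = color
    img = np.kron(img, np.ones((cell_size, cell_size, 1), dtype=np.uint8))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img).save(path)
    return path
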