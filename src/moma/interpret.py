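"""Model explanation: occlusion importance, concept classifier, concept
scores and heatmap overlays.

Region importance is measured by occlusion at the tile level: the importance
index of a region is the signed change in the predicted target-class
probability when that region's tiles are removed from the bag (the model
consumes tile features, so instance removal is the faithful analogue of
blanking the pixels; a pixel-graying mode exists behind a flag). Regions
whose (min–max normalized, by default) importance exceeds a threshold are
then described in terms of seven pathology concepts — tumor epithelium,
stroma, lymphocytes, smooth muscle, mucus, adipose, debris — by a patch
classifier; per-concept relevance is the importance-weighted sum of concept
probabilities over the selected regions, scaled so the top concept reads
100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .features import FeatureBag, RandomConvBackbone
from .synthesis import CONCEPTS

__all__ = ["ImportanceMap", "ConceptModel", "occlusion_importance",
           "train_concept_classifier", "concept_scores", "render_heatmap",
           "DEFAULT_IMPORTANCE_THRESHOLD"]

logger = logging.getLogger(__name__)

DEFAULT_IMPORTANCE_THRESHOLD = 0.7


@dataclass
class ImportanceMap:
    """Per-tile occlusion importance for one slide (signed, in [-1, 1])."""

    slide_id: str
    tile_ids: list[str]
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    importance: np.ndarray

    def __post_init__(self):
        self.importance = np.asarray(self.importance, dtype=float)
        if not (len(self.tile_ids) == self.importance.size
                == len(self.grid_rows) == len(self.grid_cols)):
            raise ValueError("importance entries must align with tiles")
        if np.any(np.abs(self.importance) > 1.0 + 1e-9):
            raise ValueError("importance must lie in [-1, 1]")

    def normalized(self) -> np.ndarray:
        """Min–max normalization of importance to [0, 1] (constant -> 0)."""
        imp = self.importance
        span = imp.max() - imp.min()
        if span == 0:
            return np.zeros_like(imp)
        return (imp - imp.min()) / span

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slide_id": self.slide_id, "tile_id": self.tile_ids,
                             "row": self.grid_rows, "col": self.grid_cols,
                             "importance": self.importance})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _tile_grid_coords(tile_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    for tid in tile_ids:
        try:
            parts = tid.rsplit("_", 2)
            rows.append(int(parts[-2][1:]))
            cols.append(int(parts[-1][1:]))
        except (IndexError, ValueError):
            rows.append(-1)
            cols.append(-1)
    return np.array(rows), np.array(cols)


def occlusion_importance(bag: FeatureBag, assignment, model,
                         target_class: int = 1) -> ImportanceMap:
    """Occlusion importance of every tile region of a slide.

    importance_i = p(target | full bag) - p(target | bag without tile i).
    The model runs in eval mode; a single-tile bag falls back to the uniform
    prior 1/n_classes for the occluded probability.
    """
    cluster_ids = (assignment.cluster_ids
                   if isinstance(assignment, ClusterAssignment) else
                   np.asarray(assignment, dtype=int))
    if hasattr(model, "eval"):
        model.eval()
    full = model.forward(bag, cluster_ids)
    p_full = float(full.class_probabilities[target_class])
    n = bag.n_tiles
    importance = np.empty(n)
    for i in range(n):
        if n == 1:
            p_occ = 1.0 / full.class_probabilities.size
        else:
            keep = np.arange(n) != i
            sub = FeatureBag(slide_id=bag.slide_id,
                             features=bag.features[keep],
                             tile_ids=[t for j, t in enumerate(bag.tile_ids) if keep[j]])
            out = model.forward(sub, cluster_ids[keep])
            p_occ = float(out.class_probabilities[target_class])
        importance[i] = p_full - p_occ
    rows, cols = _tile_grid_coords(list(bag.tile_ids))
    return ImportanceMap(slide_id=bag.slide_id, tile_ids=list(bag.tile_ids),
                         grid_rows=rows, grid_cols=cols, importance=importance)


# --------------------------------------------------------------------------
# concept classifier
# --------------------------------------------------------------------------

_CONCEPT_BACKBONE = dict(n_filters=8, kernel=5, stride=2, input_side=32,
                         pool_grid=2, seed=12345, name="concept-conv")


@dataclass
class ConceptModel:
    """Convolutional concept classifier: a frozen random-filter conv stage
    followed by a trained multinomial logistic head over the 7 concepts."""

    coef: np.ndarray  # (7, n_features)
    intercept: np.ndarray  # (7,)
    classes: list[str]
    holdout_accuracy: float = float("nan")
    per_class_accuracy: dict = field(default_factory=dict)

    def _features(self, patches: np.ndarray) -> np.ndarray:
        backbone = RandomConvBackbone(**_CONCEPT_BACKBONE)
        return backbone(patches)

    def predict_proba(self, patches) -> np.ndarray:
        """(n, 7) concept probabilities, columns ordered as CONCEPTS."""
        X = self._features(np.asarray(patches))
        logits = X @ self.coef.T + self.intercept
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        order = [self.classes.index(c) for c in CONCEPTS]
        return p[:, order]

    def predict(self, patches) -> list[str]:
        return [CONCEPTS[i] for i in np.argmax(self.predict_proba(patches), axis=1)]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, coef=self.coef, intercept=self.intercept,
                            classes=np.array(self.classes))
        path.with_suffix(".json").write_text(json.dumps(
            {"holdout_accuracy": self.holdout_accuracy,
             "per_class_accuracy": self.per_class_accuracy}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ConceptModel":
        path = Path(path)
        with np.load(path) as data:
            coef, intercept = data["coef"], data["intercept"]
            classes = [str(c) for c in data["classes"]]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(coef=coef, intercept=intercept, classes=classes,
                   holdout_accuracy=meta["holdout_accuracy"],
                   per_class_accuracy=meta["per_class_accuracy"])


def train_concept_classifier(labeled_patches, seed: int = 0,
                             holdout_fraction: float = 0.2) -> ConceptModel:
    """Train the 7-concept patch classifier on (patch, concept) pairs.

    A stratified holdout split reports held-out accuracy overall and per
    class. Deterministic given ``seed``. Raises if any of the seven concepts
    is missing from the training data.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    patches = np.stack([p for p, _ in labeled_patches])
    labels = np.array([c for _, c in labeled_patches])
    present = set(labels)
    missing = [c for c in CONCEPTS if c not in present]
    if missing:
        raise ValueError(f"missing concept classes in training data: {missing}")

    backbone = RandomConvBackbone(**_CONCEPT_BACKBONE)
    X = backbone(patches)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, test_size=holdout_fraction, random_state=seed, stratify=labels)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    acc = float(np.mean(pred == y_te))
    per_class = {c: float(np.mean(pred[y_te == c] == c))
                 for c in CONCEPTS if np.any(y_te == c)}
    return ConceptModel(coef=clf.coef_, intercept=clf.intercept_,
                        classes=list(clf.classes_), holdout_accuracy=acc,
                        per_class_accuracy=per_class)


# --------------------------------------------------------------------------
# concept scores
# --------------------------------------------------------------------------

def concept_scores(importance_map: ImportanceMap, patches,
                   concept_model: ConceptModel,
                   threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
                   scale: str = "normalized") -> dict[str, float]:
    """[0, 100]-scaled concept relevance over high-importance regions.

    Regions with importance above ``threshold`` (on the min–max normalized
    scale by default; ``scale='raw'`` thresholds the signed probability
    change directly) are scored: raw concept score = sum over selected
    regions of region importance x concept probability, then scaled so the
    maximum concept reads 100. If no region clears the threshold all scores
    are zero (with a warning).
    """
    if scale == "normalized":
        imp = importance_map.normalized()
    elif scale == "raw":
        imp = importance_map.importance
    else:
        raise ValueError("scale must be 'normalized' or 'raw'")
    patches = np.asarray(patches)
    if len(patches) != imp.size:
        raise ValueError("one patch per importance region required")
    selected = np.where(imp > threshold)[0]
    if selected.size == 0:
        logger.warning("concept_scores: no region exceeds importance "
                       "threshold %.3f; all scores zero", threshold)
        return {c: 0.0 for c in CONCEPTS}
    probs = concept_model.predict_proba(patches[selected])  # (m, 7)
    raw = (imp[selected][:, None] * probs).sum(axis=0)
    if raw.max() <= 0:
        logger.warning("concept_scores: raw scores all zero")
        return {c: 0.0 for c in CONCEPTS}
    scaled = (raw / raw.max()) * 100.0  # max concept is exactly 100
    return {c: float(s) for c, s in zip(CONCEPTS, scaled)}


# --------------------------------------------------------------------------
# heatmaps
# --------------------------------------------------------------------------

def render_heatmap(importance_map: ImportanceMap, slide_image: np.ndarray,
                   tile_size_px: int, alpha: float = 0.4,
                   out_path: str | Path | None = None) -> np.ndarray:
    """Alpha-blend a diverging color map of importance over the slide.

    Importance is mapped through matplotlib's ``coolwarm`` with a symmetric
    [-1, 1] norm (zero importance = the map's neutral near-white center); a
    vertical legend bar is appended on the right. Deterministic; optionally
    written as PNG.
    """
    from matplotlib import colormaps

    cmap = colormaps["coolwarm"]
    img = slide_image[..., :3].astype(np.float64)
    h, w = img.shape[:2]
    overlay = img.copy()
    for tid, r, c, v in zip(importance_map.tile_ids, importance_map.grid_rows,
                            importance_map.grid_cols, importance_map.importance):
        if r < 0 or c < 0:
            raise ValueError(f"tile {tid} lacks grid coordinates")
        r0, c0 = r * tile_size_px, c * tile_size_px
        if r0 + tile_size_px > h or c0 + tile_size_px > w:
            raise ValueError(f"tile {tid} does not fit the slide image")
        color = 255.0 * np.array(cmap(0.5 * (v + 1.0))[:3])
        block = overlay[r0:r0 + tile_size_px, c0:c0 + tile_size_px]
        block[:] = (1.0 - alpha) * block + alpha * color
    # legend bar: colormap gradient from +1 (top) to -1 (bottom)
    bar_w = max(8, w // 40)
    grad = np.linspace(1.0, 0.0, h)
    bar = (255.0 * np.array([cmap(g)[:3] for g in grad]))[:, None, :]
    bar = np.repeat(bar, bar_w, axis=1)
    out = np.concatenate([overlay, bar], axis=1)
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    if out_path is not None:
        import imageio.v3 as iio
        iio.imwrite(Path(out_path), out)
    return out
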