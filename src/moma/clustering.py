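"""Microenvironment clustering of tile features (k-means, K=10 default).

Tile features from the training slides are partitioned into K clusters that
stand in for recurring tissue-region types (lymphocytes, stroma, debris,
mucus, muscle, tumor, adipose, background, normal, other). The clustering is
fit globally on the training set and applied to every slide so cluster
identities are consistent across slides — the instance loss and the
per-cluster transformer streams depend on that consistency. Cluster naming
is positional only; no semantic matching to the region types is implied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .features import FeatureBag

__all__ = ["ClusterModel", "ClusterAssignment", "fit_clusters", "assign_clusters"]

DEFAULT_K = 10


@dataclass
class ClusterModel:
    centroids: np.ndarray  # (K, d)
    fit_seed: int
    training_set: str = ""

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a (K, d) matrix with K >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, centroids=self.centroids)
        meta = {"K": self.K, "fit_seed": self.fit_seed,
                "training_set": self.training_set}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        path = Path(path)
        with np.load(path) as data:
            centroids = data["centroids"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(centroids=centroids, fit_seed=meta["fit_seed"],
                   training_set=meta.get("training_set", ""))


@dataclass
class ClusterAssignment:
    slide_id: str
    tile_ids: list[str]
    cluster_ids: np.ndarray  # (n_tiles,) ints in [0, K)

    def __post_init__(self):
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        if len(self.tile_ids) != self.cluster_ids.shape[0]:
            raise ValueError("one cluster id per tile required")


def fit_clusters(bags: list[FeatureBag], K: int = DEFAULT_K,
                 seed: int = 0, n_init: int = 10,
                 training_set: str = "") -> ClusterModel:
    """Fit k-means (k-means++ init, Lloyd iterations, ``n_init`` restarts)
    on the pooled tile features of the training bags."""
    if K < 1:
        raise ValueError("K must be >= 1")
    X = np.vstack([bag.features for bag in bags])
    if X.shape[0] < K:
        raise ValueError(f"need at least K={K} tiles, got {X.shape[0]}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                random_state=seed, algorithm="lloyd")
    km.fit(X)
    return ClusterModel(centroids=km.cluster_centers_, fit_seed=seed,
                        training_set=training_set)


def assign_clusters(bag: FeatureBag, model: ClusterModel) -> ClusterAssignment:
    """Map each tile to its nearest centroid (Euclidean); exact distance ties
    break to the lowest cluster index (argmin returns the first minimum)."""
    if bag.features.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dim {bag.features.shape[1]} != centroid dim "
            f"{model.centroids.shape[1]}")
    d2 = ((bag.features[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return ClusterAssignment(slide_id=bag.slide_id, tile_ids=list(bag.tile_ids),
                             cluster_ids=np.argmin(d2, axis=1))
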