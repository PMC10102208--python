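"""Per-tile feature extraction: frozen convolutional backbones → MIL bags.

The backbone is an interface: any callable mapping a batch of RGB tiles to
fixed-length vectors. The shipped backbones are deterministic fixed-seed
random-filter convolutional extractors — random projections through a conv /
ReLU / pooled-statistics stage, a classic "random features" embedding that
is frozen by construction and runs on CPU in seconds:

- ``tiny``:    8 filters, 16-dim output; used throughout the test pipeline.
- ``default``: 64 filters with a 4x4 pooling grid, 2048-dim output, matching
  the production contract of 2048 features per patch.

No training ever happens here; permuting input tiles permutes output rows
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BackboneSpec", "FeatureBag", "RandomConvBackbone", "get_backbone",
           "extract_features", "save_bag", "load_bag"]


@dataclass
class BackboneSpec:
    name: str = "default"
    output_dim: int = 2048
    weights: str = "random-seed-0"
    deterministic: bool = True


@dataclass
class FeatureBag:
    """A slide's bag of per-tile feature vectors (rows follow tile order)."""

    slide_id: str
    features: np.ndarray  # (n_tiles, d)
    tile_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("feature bag must be a nonempty 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature bag contains non-finite values")
        if len(self.tile_ids) != self.features.shape[0]:
            raise ValueError("tile_ids must align with feature rows")
        if len(set(self.tile_ids)) != len(self.tile_ids):
            raise ValueError("tile_ids must be unique")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]


def _resize_bilinear(img: np.ndarray, side: int) -> np.ndarray:
    from skimage.transform import resize
    if img.shape[0] == side and img.shape[1] == side:
        return img.astype(np.float64) / 255.0
    return resize(img.astype(np.float64) / 255.0, (side, side, 3),
                  order=1, anti_aliasing=True, preserve_range=True)


class RandomConvBackbone:
    """Frozen random-filter conv extractor.

    Tiles are resized (bilinear) to ``input_side``, passed through
    ``n_filters`` random ``k x k x 3`` filters with stride ``stride`` and a
    ReLU, and summarized by per-filter mean and max over a ``pool_grid`` of
    spatial cells, giving ``n_filters * pool_grid^2 * 2`` features.
    """

    def __init__(self, n_filters: int, kernel: int, stride: int,
                 input_side: int, pool_grid: int, seed: int = 0,
                 name: str = "random-conv"):
        rng = np.random.default_rng(seed)
        self.filters = rng.standard_normal((n_filters, kernel, kernel, 3))
        self.filters -= self.filters.mean(axis=(1, 2, 3), keepdims=True)
        self.bias = rng.uniform(-0.2, 0.2, size=n_filters)
        self.kernel = kernel
        self.stride = stride
        self.input_side = input_side
        self.pool_grid = pool_grid
        self.output_dim = n_filters * pool_grid * pool_grid * 2
        self.spec = BackboneSpec(name=name, output_dim=self.output_dim,
                                 weights=f"random-seed-{seed}", deterministic=True)

    def _conv(self, img: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        h = (img.shape[0] - k) // s + 1
        w = (img.shape[1] - k) // s + 1
        # im2col
        windows = np.lib.stride_tricks.sliding_window_view(img, (k, k, 3))[::s, ::s, 0]
        cols = windows.reshape(h * w, k * k * 3)
        fmat = self.filters.reshape(self.filters.shape[0], -1)
        out = cols @ fmat.T + self.bias  # (h*w, n_filters)
        return np.maximum(out, 0.0).reshape(h, w, -1)

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        feats = np.empty((len(tiles), self.output_dim))
        g = self.pool_grid
        for i, tile in enumerate(tiles):
            act = self._conv(_resize_bilinear(tile, self.input_side))
            h, w, f = act.shape
            rows = np.array_split(np.arange(h), g)
            cols = np.array_split(np.arange(w), g)
            stats = []
            for rs in rows:
                for cs in cols:
                    cell = act[np.ix_(rs, cs)]
                    stats.append(cell.mean(axis=(0, 1)))
                    stats.append(cell.max(axis=(0, 1)))
            feats[i] = np.concatenate(stats)
        return feats


_BACKBONES = {
    "tiny": dict(n_filters=8, kernel=5, stride=2, input_side=32, pool_grid=1),
    "default": dict(n_filters=64, kernel=7, stride=2, input_side=64, pool_grid=4),
}


def get_backbone(name: str = "default", seed: int = 0) -> RandomConvBackbone:
    if name not in _BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; choices: {sorted(_BACKBONES)}")
    return RandomConvBackbone(**_BACKBONES[name], seed=seed, name=name)


def extract_features(tiles, backbone) -> FeatureBag:
    """Embed tissue tiles into a FeatureBag (one row per tile, input order).

    Deterministic for the shipped frozen backbones; raises on an empty tile
    list because a slide must contribute at least one tissue tile.
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("empty bag: a slide must contribute >= 1 tissue tile")
    sizes = {t.pixels.shape for t in tiles}
    if len(sizes) != 1:
        raise ValueError(f"all tiles must share one size, got {sizes}")
    feats = backbone(np.stack([t.pixels for t in tiles]))
    return FeatureBag(slide_id=tiles[0].slide_id, features=feats,
                      tile_ids=[t.tile_id for t in tiles])


def save_bag(bag: FeatureBag, path: str | Path) -> None:
    np.savez_compressed(path, slide_id=bag.slide_id, features=bag.features,
                        tile_ids=np.array(bag.tile_ids))


def load_bag(path: str | Path) -> FeatureBag:
    with np.load(path, allow_pickle=False) as data:
        return FeatureBag(slide_id=str(data["slide_id"]),
                          features=data["features"],
                          tile_ids=[str(t) for t in data["tile_ids"]])
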