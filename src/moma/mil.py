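"""The weakly-supervised slide-level predictor.

A slide's tile features form a bag. The model (i) reduces each tile feature
to ``reduced_dim`` with a shared affine map, (ii) encodes the tiles of each
microenvironment cluster as an unordered token set with a transformer
encoder (no positional encodings — bag semantics), (iii) pools tokens within
each cluster with gated attention, (iv) pools the cluster vectors with a
second gated attention into one slide embedding, and (v) classifies the
embedding with an affine head + softmax. The two-level pooling reconciles
per-cluster encoding with a single slide representation; both attention
levels are exposed, and their product gives a per-tile attention that sums
to one over the slide.

Per-tile instance scores (the classification head applied to each
post-transformer token) feed the smooth-SVM instance loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .clustering import ClusterAssignment
from .features import FeatureBag
from .nn import Tensor

__all__ = ["ModelConfig", "SlideForwardOutput", "MILClassifier", "classify"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults = the production setting:
    512-dim hidden, 8 heads, 2048-dim MLP, dropout 0.1)."""

    reduced_dim: int = 512
    transformer_hidden: int = 512
    n_heads: int = 8
    mlp_dim: int = 2048
    dropout: float = 0.1
    n_classes: int = 2
    depth: int = 2
    attention: str = "gated"  # "gated" | "simple"

    def __post_init__(self):
        if min(self.reduced_dim, self.transformer_hidden, self.mlp_dim,
               self.n_heads, self.depth) < 1:
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.attention not in ("gated", "simple"):
            raise ValueError("attention must be 'gated' or 'simple'")

    @classmethod
    def tiny(cls, n_classes: int = 2) -> "ModelConfig":
        """A CPU-friendly configuration used by tests and synthetic runs."""
        return cls(reduced_dim=16, transformer_hidden=16, n_heads=2,
                   mlp_dim=32, dropout=0.1, n_classes=n_classes, depth=1)


@dataclass
class SlideForwardOutput:
    """Forward-pass result; Tensor fields keep the autodiff graph alive for
    training, the ndarray properties are for consumers."""

    slide_id: str
    nonempty_clusters: list[int]
    class_probabilities_t: Tensor | None
    cluster_attention_t: Tensor
    tile_attention_t: Tensor
    slide_embedding_t: Tensor
    instance_scores_t: Tensor
    tile_cluster_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def class_probabilities(self) -> np.ndarray:
        return self.class_probabilities_t.data

    @property
    def cluster_attention(self) -> np.ndarray:
        return self.cluster_attention_t.data

    @property
    def tile_attention(self) -> np.ndarray:
        return self.tile_attention_t.data

    @property
    def slide_embedding(self) -> np.ndarray:
        return self.slide_embedding_t.data

    @property
    def instance_scores(self) -> np.ndarray:
        return self.instance_scores_t.data


class MILClassifier(nn.Module):
    """Cluster-structured attention-MIL classifier over feature bags."""

    def __init__(self, input_dim: int, config: ModelConfig | None = None,
                 seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        self.input_dim = input_dim
        rng = np.random.default_rng(seed)
        c = self.config
        # per-dimension input standardization (set from the training bags by
        # the training loop; identity until then)
        self.feature_mean = np.zeros(input_dim)
        self.feature_std = np.ones(input_dim)
        self.reducer = nn.Linear(input_dim, c.reduced_dim, rng)
        self.encoder = nn.TransformerEncoder(
            c.reduced_dim, c.n_heads, c.mlp_dim, c.dropout, c.depth, rng)
        attn_dim = max(8, c.reduced_dim // 2)
        gated = c.attention == "gated"
        self.tile_pool = nn.GatedAttentionPool(c.reduced_dim, attn_dim, rng, gated=gated)
        self.cluster_pool = nn.GatedAttentionPool(c.reduced_dim, attn_dim, rng, gated=gated)
        self.head = nn.Linear(c.reduced_dim, c.n_classes, rng)

    # ------------------------------------------------------------ operations
    def reduce_features(self, features) -> Tensor:
        """Shared affine map (n_tiles, input_dim) -> (n_tiles, reduced_dim)."""
        features = features.features if isinstance(features, FeatureBag) else features
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.input_dim:
            raise ValueError(f"feature dim {features.shape[1]} != model input "
                             f"dim {self.input_dim}")
        features = (features - self.feature_mean) / self.feature_std
        return self.reducer(Tensor(features))

    def set_feature_standardization(self, bags) -> None:
        """Freeze per-dimension z-scoring statistics from the training bags
        (conditioning: raw backbone activations have heterogeneous scales)."""
        X = np.vstack([b.features if hasattr(b, "features") else b for b in bags])
        self.feature_mean = X.mean(axis=0)
        self.feature_std = X.std(axis=0) + 1e-8

    def encode_and_pool(self, reduced: Tensor, cluster_ids: np.ndarray,
                        slide_id: str = "slide") -> SlideForwardOutput:
        """Transformer-encode each nonempty cluster's token set, pool tokens
        to cluster vectors and cluster vectors to the slide embedding."""
        n = reduced.shape[0]
        if n == 0:
            raise ValueError("empty bag")
        cluster_ids = np.asarray(cluster_ids, dtype=int)
        if cluster_ids.shape[0] != n:
            raise ValueError("assignment must cover every tile in the bag")
        nonempty = sorted(int(c) for c in np.unique(cluster_ids))
        cluster_vectors = []
        token_rows: list[tuple[np.ndarray, Tensor, Tensor]] = []
        for c in nonempty:
            idx = np.where(cluster_ids == c)[0]
            tokens = self.encoder(reduced[idx])
            pooled, within = self.tile_pool(tokens)
            cluster_vectors.append(pooled)
            token_rows.append((idx, tokens, within))
        cluster_mat = nn.stack(cluster_vectors, axis=0)
        slide_embedding, cluster_attention = self.cluster_pool(cluster_mat)

        # global per-tile attention = within-cluster weight * cluster weight
        tile_attn_parts, score_parts, order = [], [], []
        for j, (idx, tokens, within) in enumerate(token_rows):
            tile_attn_parts.append(within * cluster_attention[j])
            score_parts.append(self.head(tokens))
            order.append(idx)
        order = np.concatenate(order)
        inv = np.argsort(order)
        tile_attention = nn.concatenate(tile_attn_parts, axis=0)[inv]
        instance_scores = nn.concatenate(score_parts, axis=0)[inv]
        return SlideForwardOutput(
            slide_id=slide_id,
            nonempty_clusters=nonempty,
            class_probabilities_t=None,
            cluster_attention_t=cluster_attention,
            tile_attention_t=tile_attention,
            slide_embedding_t=slide_embedding,
            instance_scores_t=instance_scores,
            tile_cluster_ids=cluster_ids,
        )

    def classify(self, slide_embedding: Tensor) -> Tensor:
        """Affine head + softmax -> simplex class probabilities."""
        return nn.softmax(self.head(slide_embedding), axis=-1)

    def forward(self, bag: FeatureBag,
                assignment: ClusterAssignment | np.ndarray) -> SlideForwardOutput:
        cluster_ids = (assignment.cluster_ids
                       if isinstance(assignment, ClusterAssignment) else assignment)
        reduced = self.reduce_features(bag)
        out = self.encode_and_pool(
            reduced, cluster_ids,
            slide_id=bag.slide_id if isinstance(bag, FeatureBag) else "slide")
        out.class_probabilities_t = self.classify(out.slide_embedding_t)
        return out

    # ---------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, **self.state_dict(),
                            feature_mean=self.feature_mean,
                            feature_std=self.feature_std)
        meta = {"input_dim": self.input_dim, **vars(self.config)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MILClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        input_dim = meta.pop("input_dim")
        model = cls(input_dim, ModelConfig(**meta))
        with np.load(path) as data:
            model.feature_mean = data["feature_mean"]
            model.feature_std = data["feature_std"]
            model.load_state_dict({k: data[k] for k in data.files
                                   if not k.startswith("feature_")})
        return model.eval()


def classify(slide_embedding, head: nn.Linear) -> np.ndarray:
    """Standalone form of the classification head: affine + softmax."""
    emb = slide_embedding if isinstance(slide_embedding, Tensor) else Tensor(
        np.asarray(slide_embedding, dtype=float))
    return nn.softmax(head(emb), axis=-1).data
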