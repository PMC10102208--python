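"""Training orchestration: leakage-free splits, the classifier training
loop (bag + instance loss, SGD with cosine annealing), and 5-fold
cross-validated survival modeling.

Slides are the unit of partitioning everywhere: all tiles of a slide share
its partition so no information leaks across train/validation/test. The
classification optimizer follows the production recipe — SGD(lr 1e-3,
momentum 0.9, weight decay 5e-4), batch size 1 (one slide per step), cosine
annealing — with the epoch budget scaled to the problem at hand; survival
heads train with RMSprop on the censored Weibull likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .clustering import ClusterAssignment
from .evaluation import auroc, concordance_index, logrank_test
from .features import FeatureBag
from .losses import (InstanceLossConfig, bag_loss, inverted_class_weights,
                     select_extreme_clusters, smooth_svm_instance_loss,
                     total_loss)
from .mil import MILClassifier, ModelConfig
from .survival import LONGER, SHORTER, LinearWeibullModel

__all__ = ["TrainConfig", "split_cohort", "train_classifier",
           "cross_validate_survival"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    task: str = "classification"
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    optimizer: str = "sgd"  # sgd (classification) | rmsprop (survival)
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 250
    batch_size: int = 1
    cosine_annealing: bool = True
    seed: int = 0
    restarts: int = 3
    k_folds: int = 5
    instance_loss: InstanceLossConfig = field(default_factory=InstanceLossConfig)

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def split_cohort(manifest: pd.DataFrame,
                 fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 seed: int = 0, max_retries: int = 20) -> pd.DataFrame:
    """Slide-level train/val/test split, stratified by label when present.

    Within each label stratum: floor(fraction * n) slides go to val and
    test, the remainder to train. If any label class ends up absent from a
    partition the draw is retried (up to ``max_retries``) and then raises.
    Returns a copy of the manifest with ``partition`` filled.
    """
    if len(manifest) < 5:
        raise ValueError("need at least 5 slides to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    has_labels = manifest["label"].notna().all()
    strata = (manifest.groupby("label").groups.values()
              if has_labels else [manifest.index])
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        parts = pd.Series("train", index=manifest.index)
        for idx in strata:
            idx = np.asarray(list(idx))
            rng.shuffle(idx)
            n = idx.size
            n_val = int(np.floor(fractions[1] * n))
            n_test = int(np.floor(fractions[2] * n))
            parts[idx[:n_val]] = "val"
            parts[idx[n_val:n_val + n_test]] = "test"
        out = manifest.copy()
        out["partition"] = parts
        if not has_labels or _all_classes_present(out):
            return out
        logger.info("split_cohort: class missing from a partition, retry %d",
                    attempt + 1)
    raise ValueError("could not produce a split with every class in every "
                     "partition; cohort too small or too imbalanced")


def _all_classes_present(manifest: pd.DataFrame) -> bool:
    classes = set(manifest["label"].unique())
    return all(set(manifest.loc[manifest["partition"] == p, "label"]) == classes
               for p in ("train", "val", "test"))


def audit_no_leakage(manifest: pd.DataFrame) -> None:
    counts = manifest.groupby("slide_id")["partition"].nunique()
    if (counts > 1).any():
        raise AssertionError("slide appears in more than one partition")


# --------------------------------------------------------------------------
# classifier training
# --------------------------------------------------------------------------

def _as_ids(assignment) -> np.ndarray:
    return (assignment.cluster_ids if isinstance(assignment, ClusterAssignment)
            else np.asarray(assignment, dtype=int))


def train_classifier(train_set, val_set, model_config: ModelConfig,
                     train_config: TrainConfig) -> tuple[MILClassifier, pd.DataFrame]:
    """Train the MIL classifier on (bag, assignment, label) triples.

    One slide per optimizer step (batch size 1); per-slide loss = bag
    cross-entropy with inverted class weights + smooth-SVM instance loss on
    the attention-extreme clusters. ``restarts`` independent runs (seeds
    derived from the config seed) are trained and the one with the best
    validation AUROC is kept — the non-convex landscape of the small
    attention model has occasional bad basins, and validation-based
    selection is the model-selection rule used throughout. Within each run
    the best-validation-epoch checkpoint is restored. Returns (model,
    per-epoch log of the winning run).
    """
    best = None
    for r in range(max(1, train_config.restarts)):
        model, log = _train_single(train_set, val_set, model_config,
                                   train_config,
                                   seed=train_config.seed + 1009 * r)
        score = np.nanmax(log["val_auroc"].to_numpy()) if len(log) else np.nan
        if best is None or (not np.isnan(score) and score > best[0]):
            best = (score if not np.isnan(score) else -np.inf, model, log)
    return best[1], best[2]


def _train_single(train_set, val_set, model_config: ModelConfig,
                  train_config: TrainConfig,
                  seed: int) -> tuple[MILClassifier, pd.DataFrame]:
    train_set = list(train_set)
    val_set = list(val_set)
    if not train_set:
        raise ValueError("empty training set")
    input_dim = train_set[0][0].features.shape[1]
    model = MILClassifier(input_dim, model_config, seed=seed)
    model.set_feature_standardization([bag for bag, _, _ in train_set])

    labels = np.array([lab for _, _, lab in train_set], dtype=int)
    tile_counts = np.zeros(model_config.n_classes)
    for (bag, _, lab) in train_set:
        tile_counts[lab] += bag.n_tiles
    weights = inverted_class_weights(tile_counts)

    opt = nn.SGD(model.parameters(), lr=train_config.lr,
                 momentum=train_config.momentum,
                 weight_decay=train_config.weight_decay)
    sched = (nn.CosineAnnealingLR(opt, t_max=train_config.epochs)
             if train_config.cosine_annealing else None)
    rng = np.random.default_rng(seed)
    icfg = train_config.instance_loss

    best_state, best_auroc = None, -np.inf
    rows = []
    for epoch in range(train_config.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        bag_losses, inst_losses = [], []
        for i in order:
            bag, assignment, label = train_set[i]
            out = model.forward(bag, _as_ids(assignment))
            loss_bag = bag_loss(out.class_probabilities_t, int(label), weights)
            top, bottom = select_extreme_clusters(
                out.cluster_attention, icfg.n_top, icfg.n_bottom)
            loss_inst = _instance_loss(out, top, bottom, int(label), icfg)
            loss = total_loss(loss_bag, loss_inst)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            bag_losses.append(float(loss_bag.data))
            inst_losses.append(float(loss_inst.data))
        if sched is not None:
            sched.step()
        val_auroc = _validation_auroc(model, val_set) if val_set else np.nan
        rows.append({"epoch": epoch, "bag_loss": float(np.mean(bag_losses)),
                     "instance_loss": float(np.mean(inst_losses)),
                     "total_loss": float(np.mean(bag_losses) + np.mean(inst_losses)),
                     "val_auroc": val_auroc, "lr": opt.lr})
        if val_set and val_auroc >= best_auroc:
            best_auroc = val_auroc
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(rows)


def _instance_loss(out, top, bottom, label: int, icfg: InstanceLossConfig):
    """Smooth-SVM loss on tiles of the attention-extreme clusters; tiles in
    top clusters inherit a positive pseudo-label for the slide's class,
    bottom clusters a negative one."""
    top_set = {out.nonempty_clusters[j] for j in top}
    bottom_set = {out.nonempty_clusters[j] for j in bottom}
    sel_rows, pseudo = [], []
    for i, c in enumerate(out.tile_cluster_ids):
        if int(c) in top_set:
            sel_rows.append(i)
            pseudo.append(1.0)
        elif int(c) in bottom_set:
            sel_rows.append(i)
            pseudo.append(-1.0)
    scores = out.instance_scores_t[np.array(sel_rows)]
    return smooth_svm_instance_loss(scores, np.array(pseudo), icfg,
                                    target_class=label)


def _validation_auroc(model: MILClassifier, val_set) -> float:
    model.eval()
    scores, labels = [], []
    for bag, assignment, label in val_set:
        out = model.forward(bag, _as_ids(assignment))
        scores.append(float(out.class_probabilities[1]))
        labels.append(int(label))
    if len(set(labels)) < 2:
        return float("nan")
    return auroc(scores, labels)


# --------------------------------------------------------------------------
# survival cross-validation
# --------------------------------------------------------------------------

def cross_validate_survival(manifest: pd.DataFrame, k: int = 5,
                            seed: int = 0, lr: float = 0.05,
                            n_iter: int = 1200) -> dict:
    """Slide-level k-fold CV of the linear Weibull survival model.

    Expects a manifest with covariate columns ``x*`` plus time/event. Each
    fold trains on the others, freezes the median predicted survival index
    of the training fold as the stratification threshold, and evaluates
    c-index and the log-rank test on the held-out fold. Folds without events
    are merged into their neighbor. Returns per-fold metrics, their
    mean +- SD, and the pooled held-out stratification.
    """
    x_cols = [c for c in manifest.columns if c.startswith("x")]
    if not x_cols:
        raise ValueError("manifest has no covariate columns (x0, x1, ...)")
    records = manifest.dropna(subset=["time", "event"])
    if len(records) < k:
        raise ValueError(f"need at least k={k} slides with survival records")
    x = records[x_cols].to_numpy(float)
    time = records["time"].to_numpy(float)
    event = records["event"].to_numpy(int)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    folds = [list(f) for f in np.array_split(order, k)]
    merged = []
    for f in folds:
        if merged and event[np.array(f)].sum() == 0:
            logger.info("cross_validate_survival: merging event-free fold")
            merged[-1].extend(f)
        else:
            merged.append(f)
    fold_rows, pooled = [], []
    for i, test_idx in enumerate(merged):
        test_idx = np.array(test_idx)
        train_idx = np.setdiff1d(order, test_idx)
        model = LinearWeibullModel(len(x_cols), seed=seed).fit(
            x[train_idx], time[train_idx], event[train_idx],
            lr=lr, n_iter=n_iter)
        thr = float(np.median(model.predict_index(x[train_idx])))
        test_index = model.predict_index(x[test_idx])
        ci = concordance_index(
            pd.DataFrame({"time": time[test_idx], "event": event[test_idx]}),
            -test_index)
        groups = np.where(test_index > thr, LONGER, SHORTER)
        fold_rows.append({"fold": i, "c_index": ci,
                          "n_longer": int((groups == LONGER).sum()),
                          "n_shorter": int((groups == SHORTER).sum())})
        pooled.append(pd.DataFrame({"time": time[test_idx],
                                    "event": event[test_idx], "group": groups}))
    per_fold = pd.DataFrame(fold_rows)
    pooled_df = pd.concat(pooled, ignore_index=True)
    a = pooled_df[pooled_df["group"] == LONGER]
    b = pooled_df[pooled_df["group"] == SHORTER]
    if len(a) and len(b) and (a["event"].sum() + b["event"].sum()) > 0:
        stat, p = logrank_test(a, b)
    else:
        stat, p = float("nan"), float("nan")
    return {"per_fold": per_fold,
            "c_index_mean": float(per_fold["c_index"].mean()),
            "c_index_sd": float(per_fold["c_index"].std(ddof=1))
            if len(per_fold) > 1 else 0.0,
            "logrank_stat": stat, "logrank_p": p,
            "pooled": pooled_df}
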