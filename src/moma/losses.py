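"""Training objectives for the weakly-supervised slide models.

The classification objective is the sum of two terms:

- **bag loss** — weighted cross-entropy on the slide-level prediction, with
  inverted class weights ``w_c = N / (C * n_c)`` so minority classes are not
  drowned out;
- **instance loss** — a smoothed-hinge (smooth SVM) penalty on per-tile
  scores inside the attention-extreme clusters: the top ``n_top`` clusters
  by attention inherit a positive pseudo-label, the bottom ``n_bottom`` a
  negative one. The smoothed hinge ``l_tau(z) = tau * log(1 + exp((1-z)/tau))``
  upper-bounds the hinge ``max(0, 1-z)`` and converges to it as tau -> 0+.

The survival head is trained with the right-censored Weibull negative
log-likelihood: events contribute the log-density, censored records the
cumulative hazard ``(t / lambda) ** kappa``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "InstanceLossConfig", "WeibullParams", "inverted_class_weights",
    "bag_loss", "select_extreme_clusters", "smooth_svm_instance_loss",
    "total_loss", "weibull_negative_log_likelihood", "weibull_nll_tensor",
    "smooth_hinge",
]

logger = logging.getLogger(__name__)

LOG_EPS = 1e-12  # floor for log arguments


@dataclass
class InstanceLossConfig:
    tau: float = 1.0
    n_top: int = 3
    n_bottom: int = 3

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_top < 1 or self.n_bottom < 1:
            raise ValueError("n_top and n_bottom must be >= 1")


@dataclass
class WeibullParams:
    lam: float  # scale (lambda)
    kappa: float  # shape

    def __post_init__(self):
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("Weibull scale and shape must be strictly positive")


def inverted_class_weights(class_counts) -> np.ndarray:
    """``w_c = N_total / (C * n_c)`` — balanced so mean(w_c * n_c) = N / C."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("every class must have at least one example")
    return counts.sum() / (counts.size * counts)


def bag_loss(class_probabilities, label: int, weights) -> float:
    """Weighted cross-entropy ``-w_label * log p_label`` for one slide.

    Probabilities at or below the floor (1e-12) are clamped with a warning.
    Accepts a plain array or a Tensor (for use inside a training graph).
    """
    weights = np.asarray(weights, dtype=float)
    w = float(weights[label])
    if isinstance(class_probabilities, Tensor):
        p = class_probabilities[int(label)]
        if float(p.data) <= LOG_EPS:
            warnings.warn("bag_loss: probability clamped at epsilon")
        return (p + LOG_EPS).log() * (-w)
    p = float(np.asarray(class_probabilities)[label])
    if p <= LOG_EPS:
        warnings.warn("bag_loss: probability clamped at epsilon")
        p = LOG_EPS
    return -w * np.log(p)


def select_extreme_clusters(cluster_attention, n_top: int = 3,
                            n_bottom: int = 3) -> tuple[list[int], list[int]]:
    """Pick the attention-extreme clusters for instance supervision.

    Returns (top ids, bottom ids): the ``n_top`` highest-attention clusters
    (pseudo-label positive) and ``n_bottom`` lowest (pseudo-label negative).
    Ties in the top break to the lower cluster index, in the bottom to the
    higher index, so an all-equal attention vector yields the first n_top and
    last n_bottom indices. With fewer than ``n_top + n_bottom`` nonempty
    clusters the counts are reduced symmetrically (and logged).
    """
    a = np.asarray(cluster_attention, dtype=float)
    k = a.size
    nt, nb = n_top, n_bottom
    while nt + nb > k:
        if nt >= nb and nt > 1:
            nt -= 1
        elif nb > 1:
            nb -= 1
        else:
            raise ValueError("need at least 2 nonempty clusters")
    if (nt, nb) != (n_top, n_bottom):
        logger.info("select_extreme_clusters: reduced (top, bottom) to (%d, %d) "
                    "for %d nonempty clusters", nt, nb, k)
    desc = np.lexsort((np.arange(k), -a))       # highest a first, low index wins ties
    asc = np.lexsort((-np.arange(k), a))        # lowest a first, high index wins ties
    top = [int(i) for i in desc[:nt]]
    bottom = []
    for i in asc:
        if int(i) not in top:
            bottom.append(int(i))
        if len(bottom) == nb:
            break
    return top, bottom


def smooth_hinge(z, tau: float):
    """``l_tau(z) = tau * log(1 + exp((1 - z) / tau))`` (elementwise).

    An upper bound on the hinge max(0, 1-z) that converges to it pointwise
    as tau -> 0+. Works on arrays and Tensors.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if isinstance(z, Tensor):
        return ((1.0 - z) * (1.0 / tau)).softplus() * tau
    return tau * np.logaddexp(0.0, (1.0 - np.asarray(z, dtype=float)) / tau)


def smooth_svm_instance_loss(instance_scores, pseudo_labels,
                             config: InstanceLossConfig,
                             target_class: int = 1):
    """Mean smoothed-hinge loss over the pseudo-labeled tiles.

    ``instance_scores`` is (n_tiles, n_classes); ``pseudo_labels`` is +-1 per
    tile (from the attention-extreme clusters). The binary margin is
    ``z_i = y_i * (s_target - s_other)``; with more than two classes,
    ``s_other`` is the strongest non-target score (one-vs-rest form).
    Accepts arrays or Tensors.
    """
    labels = np.asarray(pseudo_labels, dtype=float)
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise ValueError("pseudo labels must be +-1")
    is_tensor = isinstance(instance_scores, Tensor)
    raw = instance_scores.data if is_tensor else np.asarray(instance_scores, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != labels.size:
        raise ValueError("instance_scores must be (n_tiles, n_classes) aligned "
                         "with pseudo_labels")
    n_classes = raw.shape[1]
    other = np.array([c for c in range(n_classes) if c != target_class])
    # strongest competing class per tile, chosen on values (one-vs-rest)
    other_idx = other[np.argmax(raw[:, other], axis=1)]
    rows = np.arange(raw.shape[0])
    if is_tensor:
        s_t = instance_scores[rows, np.full(raw.shape[0], target_class)]
        s_o = instance_scores[rows, other_idx]
        z = (s_t - s_o) * labels
        return smooth_hinge(z, config.tau).mean()
    z = (raw[rows, target_class] - raw[rows, other_idx]) * labels
    return float(np.mean(smooth_hinge(z, config.tau)))


def total_loss(bag, instance):
    """Unweighted sum of the bag and instance terms."""
    return bag + instance


def weibull_negative_log_likelihood(params: WeibullParams, time: float,
                                    event: int) -> float:
    """Right-censored Weibull NLL for one record.

    event=1: ``-[log(kappa/lambda) + (kappa-1) log(t/lambda) - (t/lambda)^kappa]``
    event=0: ``(t/lambda)^kappa`` (the cumulative hazard).
    """
    if time <= 0:
        raise ValueError("time must be positive")
    if event not in (0, 1):
        raise ValueError("event must be 0 or 1")
    lam, kappa = params.lam, params.kappa
    z = time / lam
    cum_hazard = z**kappa
    if event == 0:
        return float(cum_hazard)
    return float(-(np.log(max(kappa / lam, LOG_EPS))
                   + (kappa - 1.0) * np.log(max(z, LOG_EPS)) - cum_hazard))


def weibull_nll_tensor(lam: Tensor, kappa: Tensor, time, event) -> Tensor:
    """Vectorized Tensor form of the censored Weibull NLL (mean over records).

    ``lam`` and ``kappa`` broadcast against 1-D ``time``/``event`` arrays;
    used to train the survival head by gradient descent.
    """
    time = np.atleast_1d(np.asarray(time, dtype=float))
    event = np.atleast_1d(np.asarray(event, dtype=float))
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    log_z = Tensor(np.log(time)) - (lam + LOG_EPS).log()
    cum_hazard = (kappa * log_z).exp()
    log_density = (kappa + LOG_EPS).log() - (lam + LOG_EPS).log() \
        + (kappa - 1.0) * log_z - cum_hazard
    nll = cum_hazard - Tensor(event) * (log_density + cum_hazard)
    return nll.mean()
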