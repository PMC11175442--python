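"""Segmentation and classification losses.

The segmentation loss is the multi-class focal loss

    L_focal = -(1/N) sum_n sum_c (1 - p_hat_{n,c})^gamma  y_{n,c} log p_hat_{n,c}

i.e. cross-entropy down-weighted on well-classified time stamps; gamma = 0
recovers plain cross-entropy and gamma defaults to 1.  The classifier
branch uses binary cross-entropy on its two-way softmax, and the training
objective is ``L_focal + alpha * L_bce`` with alpha defaulting to 1.

Each loss exists in two forms: a plain numpy function on probability
maps/labels (the public API) and a Tensor form used inside the training
loop so gradients flow through the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import nn
from .types import ClassProbMap, ConsistencyError, LabelMask, RhythmProb


@dataclass
class LossConfig:
    gamma: float = 1.0
    alpha: float = 1.0
    log_floor: float = 1e-7

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.alpha < 0 or self.log_floor <= 0:
            raise ConsistencyError("gamma, alpha must be >= 0 and log_floor > 0")


def _as_probs(probs: Union[ClassProbMap, np.ndarray]) -> np.ndarray:
    return probs.probs if isinstance(probs, ClassProbMap) else np.asarray(probs, float)


def _as_labels(labels: Union[LabelMask, np.ndarray]) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelMask) else np.asarray(labels)


def focal_loss(
    probs: Union[ClassProbMap, np.ndarray],
    labels: Union[LabelMask, np.ndarray],
    gamma: float = 1.0,
    log_floor: float = 1e-7,
) -> float:
    """Mean focal loss over time stamps (non-negative scalar)."""
    p = _as_probs(probs)
    y = _as_labels(labels)
    if p.shape[0] != y.shape[0]:
        raise ConsistencyError(
            f"probability map has {p.shape[0]} samples but labels have {y.shape[0]}"
        )
    pt = p[np.arange(y.size), y]
    return float(np.mean((1.0 - pt) ** gamma * -np.log(np.maximum(pt, log_floor))))


def classification_loss(rhythm: RhythmProb, is_af: bool, log_floor: float = 1e-7) -> float:
    """Binary cross-entropy of the two-way rhythm softmax."""
    p_true = rhythm.p_af if is_af else rhythm.p_other
    return float(-np.log(max(p_true, log_floor)))


def total_loss(focal: float, bce: float, alpha: float = 1.0):
    """Hybrid objective: segmentation focal loss plus alpha x classification BCE."""
    return focal + alpha * bce


# ---------------------------------------------------------------------------
# Tensor forms (training)
# ---------------------------------------------------------------------------


def focal_loss_t(seg_probs: nn.Tensor, labels: np.ndarray, gamma: float,
                 log_floor: float) -> nn.Tensor:
    """Focal loss on (N, 4, L) probabilities and (N, L) integer labels."""
    pt = nn.gather_channel(seg_probs, labels)
    neg_log = -(pt.clip_min(log_floor).log())
    if gamma == 0.0:
        return neg_log.mean()
    weight = ((1.0 - pt).clip_min(0.0)) ** gamma
    return (weight * neg_log).mean()


def bce_loss_t(rhythm_probs: nn.Tensor, is_af: np.ndarray, log_floor: float) -> nn.Tensor:
    """Two-class cross-entropy on (N, 2) softmax output; channel 1 = AF."""
    labels = np.asarray(is_af, dtype=np.int64)[:, None]
    n = rhythm_probs.shape[0]
    p3 = rhythm_probs.reshape(n, 2, 1)
    pt = nn.gather_channel(p3, labels)
    return -(pt.clip_min(log_floor).log()).mean()
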