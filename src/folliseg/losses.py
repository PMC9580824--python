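"""Mask loss, class-balanced edge loss and their weighted combination.

The training objective couples a region term on the predicted follicle mask
with a boundary term on edge maps:

    L_joint = lambda1 * L_mask + lambda2 * L_edge

``L_mask`` is the mean per-pixel binary cross-entropy between the predicted
probability map and the ground-truth mask (a soft Dice loss is available as
an alternative).  ``L_edge`` is a cross-entropy between a predicted edge map
and the Canny edge map of the ground-truth mask, re-weighted by the class
balance of edge versus non-edge pixels: with ``Y`` the pixel set, ``Y+`` its
edge pixels and ``beta = |Y-| / |Y|``,

    L_edge = -(1/|Y|) [ beta * sum_{j in Y+} log p_j
                        + (1 - beta) * sum_{j in Y-} log(1 - p_j) ]

Edge pixels are a tiny minority in ultrasound masks, so the balance factor
keeps the positive term from being drowned out.  Probabilities are clamped
to ``[EPS, 1 - EPS]`` before logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "LossWeights",
    "LossBreakdown",
    "mask_loss",
    "dice_loss",
    "balanced_edge_loss",
    "balanced_edge_loss_grad",
    "joint_loss",
]

#: Clamping margin applied to probabilities before taking logarithms.
EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weight factors of the joint loss (both >= 0, not both zero)."""

    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("loss weights must be finite")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda1 == 0 and self.lambda2 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class LossBreakdown:
    """Individual loss terms and their weighted sum, kept for logging."""

    mask_loss: float
    edge_loss: float
    joint: float


def _check_pair(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")
    return pred, target


def mask_loss(pred_prob: np.ndarray, gt: np.ndarray) -> float:
    """Mean binary cross-entropy between a probability map and a binary mask."""
    pred, gt = _check_pair(pred_prob, gt)
    p = np.clip(pred, EPS, 1.0 - EPS)
    return float(-np.mean(gt * np.log(p) + (1.0 - gt) * np.log(1.0 - p)))


def dice_loss(pred_prob: np.ndarray, gt: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2 |P.G| + s) / (|P| + |G| + s)`` — config alternative."""
    pred, gt = _check_pair(pred_prob, gt)
    inter = float(np.sum(pred * gt))
    denom = float(np.sum(pred) + np.sum(gt))
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def balanced_edge_loss(pred_edge: np.ndarray, gt_edge: np.ndarray) -> float:
    """Class-balanced cross-entropy between an edge-strength map and a binary edge map.

    With ``beta = |Y-|/|Y|`` (the non-edge fraction of the label), the
    positive (edge) term is weighted by ``beta`` and the negative term by
    ``1 - beta``, so a sparse edge class is not swamped.  When the label is
    all edges or all non-edges one term vanishes and the other keeps its
    weight; when both classes have equal size the loss reduces to half the
    unweighted mean cross-entropy.
    """
    pred, gt = _check_pair(pred_edge, gt_edge)
    if not np.isin(gt, (0.0, 1.0)).all():
        raise ValueError("ground-truth edge map must be binary")
    p = np.clip(pred, EPS, 1.0 - EPS)
    n = gt.size
    n_pos = float(gt.sum())
    beta = (n - n_pos) / n
    pos_term = beta * np.sum(gt * np.log(p))
    neg_term = (1.0 - beta) * np.sum((1.0 - gt) * np.log(1.0 - p))
    return float(-(pos_term + neg_term) / n)


def balanced_edge_loss_grad(pred_edge: np.ndarray, gt_edge: np.ndarray) -> np.ndarray:
    """Gradient of :func:`balanced_edge_loss` w.r.t. the predicted edge map.

    Zero where the prediction sits outside the clamp interval (the clamp is
    flat there), matching the value computed by the forward function.
    """
    pred, gt = _check_pair(pred_edge, gt_edge)
    p = np.clip(pred, EPS, 1.0 - EPS)
    n = gt.size
    beta = (n - float(gt.sum())) / n
    grad = -(beta * gt / p - (1.0 - beta) * (1.0 - gt) / (1.0 - p)) / n
    inside = (pred > EPS) & (pred < 1.0 - EPS)
    return np.where(inside, grad, 0.0)


def joint_loss(mask_l: float, edge_l: float, w: LossWeights) -> LossBreakdown:
    """Combine mask and edge terms: ``joint = lambda1 * mask + lambda2 * edge``."""
    if mask_l < 0 or edge_l < 0:
        raise ValueError("loss terms must be non-negative")
    return LossBreakdown(
        mask_loss=float(mask_l),
        edge_loss=float(edge_l),
        joint=float(w.lambda1 * mask_l + w.lambda2 * edge_l),
    )
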