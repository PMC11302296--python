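"""Training objective: class-weighted cross-entropy on the 2-class molecule
output plus generalized dice on the 3-class voxel segmentation.

The overall loss is the plain sum L_ovr = L_ce + L_gen_dice with no
rebalancing coefficient.

The generalized dice follows Sudre et al. (2017): per-class weights
w_c = 1 / (Σ_voxels y_c)², so rare reactivity classes (the ~10% tails of
the electronegativity distribution) count as much as the dominant
background class, and

    L_gen_dice = 1 − (2 Σ_c w_c Σ_v y_cv ŷ_cv + ε) / (Σ_c w_c Σ_v (y_cv + ŷ_cv) + ε)

with ŷ the softmax-normalized per-voxel class scores and ε a small
smoothing constant placed in both numerator and denominator. A class absent
from the ground truth would get infinite weight; such weights are replaced
by the largest finite class weight of that sample (zero if every class is
empty) so false positives on absent classes are still penalized and no
exception or NaN arises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .autodiff import Tensor, log_softmax
from .cube import TernaryMask

__all__ = ["LossWeights", "weighted_cross_entropy", "generalized_dice_loss",
           "combined_loss"]


@dataclass(frozen=True)
class LossWeights:
    ce_class_weights: Tuple[float, float] = (1.0, 1.0)
    epsilon: float = 1e-5
    reduction: str = "weighted-mean"  # weighted-mean | mean | sum

    def __post_init__(self):
        if any(w <= 0 for w in self.ce_class_weights):
            raise ValueError("class weights must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.reduction not in ("weighted-mean", "mean", "sum"):
            raise ValueError(f"unknown reduction {self.reduction!r}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def weighted_cross_entropy(
    class_scores, labels, weights: LossWeights = LossWeights()
) -> Tensor:
    """Weighted negative log-likelihood of the true class.

    ``class_scores`` are unnormalized scores, shape (N, 2); they are
    softmax-normalized internally. Each sample contributes
    w_{label} · (−log p_label); the default reduction divides by the sum of
    the applied weights (weighted mean), which makes the loss invariant to
    a common rescaling of both class weights.
    """
    scores = _as_tensor(class_scores)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ValueError(
            f"scores shape {scores.shape} inconsistent with {labels.shape[0]} labels"
        )
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= scores.shape[1]:
        raise ValueError("labels out of range")
    logp = log_softmax(scores, axis=1)
    onehot = np.zeros(scores.shape, dtype=scores.data.dtype)
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    per_sample = -(logp * onehot).sum(axis=1)  # (N,)
    w = np.asarray(weights.ce_class_weights, dtype=scores.data.dtype)[labels]
    weighted = per_sample * w
    if weights.reduction == "sum":
        return weighted.sum()
    if weights.reduction == "mean":
        return weighted.mean()
    return weighted.sum() * (1.0 / float(w.sum()))


def _mask_batch_to_onehot(true_mask, n_classes: int = 3) -> np.ndarray:
    """(N, D, H, W) int labels or sequence of TernaryMask → (N, C, D, H, W)."""
    if isinstance(true_mask, TernaryMask):
        true_mask = [true_mask]
    if isinstance(true_mask, (list, tuple)) and true_mask and isinstance(
        true_mask[0], TernaryMask
    ):
        lab = np.stack([m.labels for m in true_mask])
    else:
        lab = np.asarray(true_mask)
    if lab.ndim == 3:
        lab = lab[None]
    return np.stack([(lab == c) for c in range(n_classes)], axis=1).astype(np.float64)


def generalized_dice_loss(
    seg_scores, true_mask, epsilon: float = 1e-5
) -> Tensor:
    """Generalized dice with squared-reciprocal-volume class weights.

    ``seg_scores``: (N, 3, D, H, W) unnormalized scores; ``true_mask``:
    integer labels (N, D, H, W) / a (list of) TernaryMask. Averaged over
    the batch.
    """
    scores = _as_tensor(seg_scores)
    if scores.ndim == 4:
        scores = scores.reshape(1, *scores.shape)
    y = _mask_batch_to_onehot(true_mask).astype(scores.data.dtype)
    if y.shape != scores.shape:
        raise ValueError(
            f"mask one-hot shape {y.shape} != scores shape {scores.shape}"
        )
    vox_axes = (2, 3, 4)
    yhat = log_softmax(scores, axis=1).exp()
    ground_o = y.sum(axis=vox_axes)  # (N, C) — ground-truth class volumes
    with np.errstate(divide="ignore"):
        w = 1.0 / ground_o**2
    inf = np.isinf(w)
    w[inf] = 0.0
    row_max = w.max(axis=1, keepdims=True)
    w = np.where(inf, row_max, w)  # absent classes inherit the largest weight
    intersect = (yhat * y).sum(axis=vox_axes)  # (N, C)
    pred_o = yhat.sum(axis=vox_axes)  # (N, C)
    numer = (intersect * w).sum(axis=1) * 2.0 + epsilon
    denom = (pred_o * w).sum(axis=1) + (ground_o * w).sum(axis=1) + epsilon
    loss = 1.0 - numer * denom**-1.0
    return loss.mean()


def combined_loss(
    class_scores, labels, seg_scores, true_mask, weights: LossWeights = LossWeights()
) -> Tensor:
    """L_ovr = L_ce + L_gen_dice — the exact sum, no rebalancing."""
    return weighted_cross_entropy(class_scores, labels, weights) + \
        generalized_dice_loss(seg_scores, true_mask, weights.epsilon)
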