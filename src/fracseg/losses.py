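"""Distance-weighted segmentation losses and the smooth-transition schedule.

The fracture network trains with a weighted sum of a distance-weighted
soft Dice and a distance-weighted cross-entropy:

    L_dice  = 1 - (2/|L|) * sum_l  (sum_v W^_v P_vl Y_vl) /
                                   (sum_v W^_v P_vl + sum_v W^_v Y_vl)
    L_ce    = -(1/(|V||L|)) * sum_v sum_l W^_v Y_vl log P_vl
    L_total = lambda_dice * L_dice + lambda_ce * L_ce

A smooth transition blends the all-ones weight matrix J into the FDM
weights over training time, so the model first learns global shape and
only then focuses on the fracture surface:

    W_st = J                                  for t < tau_begin
         = J/(1+delta) + W^ * delta/(1+delta) for tau_begin <= t <= tau_begin+tau_smooth
         = W^                                 for t > tau_begin+tau_smooth
    delta = -ln(1 - (t - tau_begin)/tau_smooth + eps)

Deep supervision sums the per-level total losses with fixed aggregation
coefficients, each level using its own (downsampled, renormalized) weights.

Everything here operates on arrays of shape (L, *spatial): ``P`` softmax
probabilities, ``Y`` one-hot ground truth, ``W_hat`` per-voxel weights of
shape ``spatial``.  Gradients w.r.t. ``P`` are provided analytically for
the numpy training loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LossConfig",
    "TransitionSchedule",
    "weighted_dice_loss",
    "weighted_ce_loss",
    "total_loss",
    "total_loss_grad",
    "transition_weight",
    "transition_mix",
    "deep_supervision_loss",
    "one_hot",
]

_P_CLIP = 1e-7
_DICE_SMOOTH = 1e-5


@dataclass
class LossConfig:
    """Balancing weights of the two loss terms (both default to 1)."""

    lambda_dice: float = 1.0
    lambda_ce: float = 1.0
    #: None = all classes (background included) enter the Dice average
    class_set: Optional[Sequence[int]] = None
    dice_smooth: float = _DICE_SMOOTH

    def __post_init__(self):
        if self.lambda_dice < 0 or self.lambda_ce < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_dice == 0 and self.lambda_ce == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class TransitionSchedule:
    """When and how fast uniform weights give way to FDM weights.

    ``time_unit`` is bookkeeping only: ``t`` passed to
    :func:`transition_weight` must be in the same unit as ``tau_begin`` /
    ``tau_smooth`` (epochs by default).
    """

    tau_begin: float = 0.0
    tau_smooth: float = 1000.0
    epsilon: float = 1e-6
    time_unit: str = "epoch"

    def __post_init__(self):
        if self.tau_begin < 0 or self.tau_smooth < 0:
            raise ValueError("tau_begin and tau_smooth must be >= 0")
        if not (0.0 < self.epsilon <= 1e-3):
            raise ValueError("epsilon must be in (0, 1e-3]")
        if self.time_unit not in ("epoch", "iteration"):
            raise ValueError("time_unit must be 'epoch' or 'iteration'")


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer label grid -> one-hot array of shape (n_classes, *spatial)."""
    Y = np.zeros((n_classes,) + labels.shape, dtype=np.float64)
    for l in range(n_classes):
        Y[l] = labels == l
    return Y


def _check_shapes(P, Y, W_hat):
    if P.shape != Y.shape:
        raise ValueError(f"prediction shape {P.shape} != ground truth shape {Y.shape}")
    if W_hat.shape != P.shape[1:]:
        raise ValueError(f"weight shape {W_hat.shape} != spatial shape {P.shape[1:]}")


def _class_indices(cfg: Optional[LossConfig], n_classes: int):
    if cfg is None or cfg.class_set is None:
        return list(range(n_classes))
    return list(cfg.class_set)


def weighted_dice_loss(P: np.ndarray, Y: np.ndarray, W_hat: np.ndarray,
                       cfg: Optional[LossConfig] = None) -> float:
    """Distance-weighted soft Dice loss, averaged over classes; in [0, 1]."""
    _check_shapes(P, Y, W_hat)
    smooth = cfg.dice_smooth if cfg is not None else _DICE_SMOOTH
    classes = _class_indices(cfg, P.shape[0])
    acc = 0.0
    for l in classes:
        num = float((W_hat * P[l] * Y[l]).sum()) + smooth
        den = float((W_hat * P[l]).sum() + (W_hat * Y[l]).sum()) + smooth
        acc += num / den
    return 1.0 - (2.0 / len(classes)) * acc


def weighted_ce_loss(P: np.ndarray, Y: np.ndarray, W_hat: np.ndarray,
                     cfg: Optional[LossConfig] = None) -> float:
    """Distance-weighted cross-entropy, with the 1/(|V||L|) normalization."""
    _check_shapes(P, Y, W_hat)
    L = P.shape[0]
    n_vox = int(np.prod(P.shape[1:]))
    Pc = np.clip(P, _P_CLIP, 1.0)
    return float(-(W_hat[None] * Y * np.log(Pc)).sum() / (n_vox * L))


def total_loss(P: np.ndarray, Y: np.ndarray, W_hat: np.ndarray,
               cfg: Optional[LossConfig] = None) -> float:
    """lambda_dice * L_dice + lambda_ce * L_ce."""
    cfg = cfg or LossConfig()
    out = 0.0
    if cfg.lambda_dice > 0:
        out += cfg.lambda_dice * weighted_dice_loss(P, Y, W_hat, cfg)
    if cfg.lambda_ce > 0:
        out += cfg.lambda_ce * weighted_ce_loss(P, Y, W_hat, cfg)
    return out


def total_loss_grad(P: np.ndarray, Y: np.ndarray, W_hat: np.ndarray,
                    cfg: Optional[LossConfig] = None) -> Tuple[float, np.ndarray]:
    """Loss value and its analytic gradient w.r.t. the probabilities ``P``."""
    cfg = cfg or LossConfig()
    _check_shapes(P, Y, W_hat)
    L = P.shape[0]
    n_vox = int(np.prod(P.shape[1:]))
    grad = np.zeros_like(P)
    value = 0.0
    if cfg.lambda_dice > 0:
        smooth = cfg.dice_smooth
        classes = _class_indices(cfg, L)
        acc = 0.0
        for l in classes:
            num = float((W_hat * P[l] * Y[l]).sum()) + smooth
            den = float((W_hat * P[l]).sum() + (W_hat * Y[l]).sum()) + smooth
            acc += num / den
            # d/dP_vl of num/den = (Y*W*den - num*W) / den^2
            grad[l] += cfg.lambda_dice * (-2.0 / len(classes)) * (
                (Y[l] * W_hat * den - num * W_hat) / (den * den)
            )
        value += cfg.lambda_dice * (1.0 - (2.0 / len(classes)) * acc)
    if cfg.lambda_ce > 0:
        Pc = np.clip(P, _P_CLIP, 1.0)
        value += cfg.lambda_ce * float(-(W_hat[None] * Y * np.log(Pc)).sum() / (n_vox * L))
        inside = (P >= _P_CLIP) & (P <= 1.0)
        grad += cfg.lambda_ce * np.where(inside, -(W_hat[None] * Y) / Pc, 0.0) / (n_vox * L)
    return value, grad


def transition_mix(t: float, sched: TransitionSchedule) -> float:
    """Mixing coefficient on the FDM weights W^ at training time ``t``.

    0 before the transition starts, 1 after it ends, delta/(1+delta) in
    between with delta = -ln(1 - (t - tau_begin)/tau_smooth + eps).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t < sched.tau_begin:
        return 0.0
    if sched.tau_smooth == 0 or t > sched.tau_begin + sched.tau_smooth:
        return 1.0
    frac = (t - sched.tau_begin) / sched.tau_smooth
    delta = -np.log(max(1.0 - frac + sched.epsilon, np.finfo(float).tiny))
    if delta < 0:  # t == tau_begin with eps > 0 gives a tiny negative log argument margin
        delta = 0.0
    return float(delta / (1.0 + delta))


def transition_weight(t: float, sched: TransitionSchedule, W_hat: np.ndarray) -> np.ndarray:
    """Blend the all-ones matrix J into the FDM weights at training time ``t``."""
    m = transition_mix(t, sched)
    if m == 0.0:
        return np.ones_like(W_hat)
    if m == 1.0:
        return W_hat.copy()
    return (1.0 - m) + m * W_hat


def deep_supervision_loss(
    preds: List[np.ndarray],
    labels: List[np.ndarray],
    weights: List[np.ndarray],
    t: float,
    sched: Optional[TransitionSchedule] = None,
    cfg: Optional[LossConfig] = None,
    level_loss_weights: Optional[Sequence[float]] = None,
    return_grads: bool = False,
):
    """Aggregate per-level losses: sum_n a_n * L_total at level n.

    ``preds[n]``: (L, *spatial_n) probabilities; ``labels[n]``: one-hot of
    the same shape; ``weights[n]``: normalized FDM weights of shape
    ``spatial_n``.  The smooth transition is applied at every level.
    """
    if not (len(preds) == len(labels) == len(weights)):
        raise ValueError("preds, labels and weights must have the same number of levels")
    n = len(preds)
    if level_loss_weights is None:
        a = np.array([2.0 ** (-k) for k in range(n)])
        level_loss_weights = a / a.sum()
    if len(level_loss_weights) != n:
        raise ValueError("level_loss_weights length mismatch")
    cfg = cfg or LossConfig()
    total = 0.0
    grads = []
    for k in range(n):
        Wk = weights[k] if sched is None else transition_weight(t, sched, weights[k])
        if return_grads:
            lk, gk = total_loss_grad(preds[k], labels[k], Wk, cfg)
            grads.append(level_loss_weights[k] * gk)
        else:
            lk = total_loss(preds[k], labels[k], Wk, cfg)
        total += level_loss_weights[k] * lk
    if return_grads:
        return total, grads
    return total
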