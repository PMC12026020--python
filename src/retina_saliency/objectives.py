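"""Composite training objective: focal loss + mean squared error.

The focal term addresses the extreme class imbalance of dense saliency
targets (salient pixels are rare) by down-weighting well-classified pixels
with the factor ``(1 − pt)^γ``; the MSE term enforces pixel-wise intensity
agreement. The total objective is their unweighted sum.

Ground-truth saliency targets are continuous (blurred fixation densities),
so the focal term is extended to soft targets by the convex combination
``t·FL(p, 1) + (1 − t)·FL(p, 0)`` per pixel, which reduces to the usual
binary focal loss when ``t ∈ {0, 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Predictions are clipped to [EPS, 1 − EPS] before taking logarithms.
EPS = 1e-7


@dataclass(frozen=True)
class LossParams:
    """Focal-loss hyperparameters.

    ``gamma`` is the focusing parameter (default 2): larger values
    concentrate the loss on hard, misclassified pixels. ``alpha`` is the
    balancing factor (default 0.25) weighting the rare positive class.
    """

    gamma: float = 2.0
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _validate_pair(pred, target) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def focal_loss(pred, target, params: LossParams | None = None) -> float:
    """Pixel-mean focal loss ``−α·(1−pt)^γ·ln(pt)`` with soft-target support.

    ``pt`` is the predicted probability of the true class: ``pred`` where the
    target is 1 and ``1 − pred`` where it is 0; fractional targets mix the
    two terms linearly. Predictions and targets are expected in ``[0, 1]``.
    """
    if params is None:
        params = LossParams()
    pred, target = _validate_pair(pred, target)
    if target.min() < 0 or target.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    p = np.clip(pred, EPS, 1.0 - EPS)
    pos = -params.alpha * (1.0 - p) ** params.gamma * np.log(p)
    neg = -params.alpha * p**params.gamma * np.log(1.0 - p)
    return float(np.mean(target * pos + (1.0 - target) * neg))


def mse_loss(pred, target) -> float:
    """Pixel-mean squared difference."""
    pred, target = _validate_pair(pred, target)
    return float(np.mean((pred - target) ** 2))


def total_loss(pred, target, params: LossParams | None = None) -> float:
    """Composite objective: focal loss plus MSE, unweighted."""
    return focal_loss(pred, target, params) + mse_loss(pred, target)
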