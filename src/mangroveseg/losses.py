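"""Training objectives: focal loss, soft Dice (F-beta) loss, and their sum.

Focal loss is cross-entropy modulated by ``alpha * (1 - pr)**gamma``,
down-weighting easy pixels so the minority mangrove classes are not
swamped by the dominant water/aquaculture classes. Dice loss is one minus
the F-beta combination of *soft* precision and recall, computed per class
from probability mass over the whole batch; hard-count precision/recall
live in :mod:`mangroveseg.metrics`. The combined objective is their sum.

Defaults alpha=0.25, gamma=2, beta=1.

Reduction order (it changes gradient scale, so it is fixed and documented):
focal sums over classes and averages over pixels and batch; Dice averages
over the classes present in the ground truth.

Each loss has a companion ``*_grad`` returning (value, d value / d pr) so
the segmentation model can backpropagate without an autodiff framework;
the gradients are exercised against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LossParams:
    """alpha: class-balance factor; gamma: focusing exponent; beta:
    precision/recall trade-off in the Dice term; epsilon: smoothing."""

    alpha: float = 0.25
    gamma: float = 2.0
    beta: float = 1.0
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class PredictionBatch:
    """Validated (one-hot ground truth, predicted probabilities) pair.

    Both arrays share a shape (..., C): arbitrary pixel/batch leading
    dimensions with classes last.
    """

    gt: np.ndarray
    pr: np.ndarray

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.float64)
        self.pr = np.asarray(self.pr, dtype=np.float64)
        if self.gt.shape != self.pr.shape:
            raise ValueError(
                f"gt shape {self.gt.shape} != pr shape {self.pr.shape}"
            )
        if self.gt.ndim < 2:
            raise ValueError("batch arrays must be at least 2-D (..., C)")
        if self.pr.min() < -1e-6 or self.pr.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.pr.sum(axis=-1), 1.0, atol=1e-5):
            raise ValueError("probabilities must sum to 1 over classes")
        onehot = (self.gt == 1).sum(axis=-1) == 1
        if not (onehot & ((self.gt == 0) | (self.gt == 1)).all(axis=-1)).all():
            raise ValueError("ground truth must be one-hot per pixel")


def _unpack(batch, pr):
    if pr is None:
        if not isinstance(batch, PredictionBatch):
            raise TypeError("pass a PredictionBatch or (gt, pr) arrays")
        return batch.gt, batch.pr
    gt = np.asarray(batch, dtype=np.float64)
    pr = np.asarray(pr, dtype=np.float64)
    if gt.shape != pr.shape:
        raise ValueError(f"gt shape {gt.shape} != pr shape {pr.shape}")
    return gt, pr


def _npix(gt: np.ndarray) -> int:
    return int(np.prod(gt.shape[:-1]))


def focal_loss(batch, pr=None, params: LossParams = LossParams()) -> float:
    """Mean over pixels of sum_c  -gt * alpha * (1 - pr)^gamma * ln(pr + eps)."""
    gt, pr = _unpack(batch, pr)
    a, g, e = params.alpha, params.gamma, params.epsilon
    term = -gt * a * (1.0 - pr) ** g * np.log(pr + e)
    return float(term.sum() / _npix(gt))


def focal_loss_grad(batch, pr=None, params: LossParams = LossParams()):
    gt, pr = _unpack(batch, pr)
    a, g, e = params.alpha, params.gamma, params.epsilon
    one_m = 1.0 - pr
    value = float((-gt * a * one_m**g * np.log(pr + e)).sum() / _npix(gt))
    # d/dp [-a (1-p)^g ln(p+e)] = a g (1-p)^(g-1) ln(p+e) - a (1-p)^g / (p+e)
    if g == 0:
        focusing = 0.0  # the (1-p)^(g-1) term carries a factor g
    else:
        with np.errstate(divide="ignore"):
            focusing = g * one_m ** (g - 1.0) * np.log(pr + e)
    d = gt * a * (focusing - one_m**g / (pr + e))
    return value, d / _npix(gt)


def _dice_terms(gt, pr, params):
    """Per-class soft intersection / prediction mass / reference mass,
    summed over every leading dimension."""
    axes = tuple(range(gt.ndim - 1))
    inter = (gt * pr).sum(axis=axes)
    pred_mass = pr.sum(axis=axes)
    ref_mass = gt.sum(axis=axes)
    return inter, pred_mass, ref_mass


def dice_loss(batch, pr=None, params: LossParams = LossParams()) -> float:
    """1 - F_beta(soft precision, soft recall), averaged over the classes
    present in the ground truth."""
    gt, pr = _unpack(batch, pr)
    b2, e = params.beta**2, params.epsilon
    inter, pred_mass, ref_mass = _dice_terms(gt, pr, params)
    present = ref_mass > 0
    p = inter / (pred_mass + e)
    r = inter / (ref_mass + e)
    f = (1.0 + b2) * p * r / (b2 * p + r + e)
    return float(np.mean(1.0 - f[present]))


def dice_loss_grad(batch, pr=None, params: LossParams = LossParams()):
    gt, pr = _unpack(batch, pr)
    b2, e = params.beta**2, params.epsilon
    inter, pred_mass, ref_mass = _dice_terms(gt, pr, params)
    present = ref_mass > 0
    n_def = int(present.sum())
    p = inter / (pred_mass + e)
    r = inter / (ref_mass + e)
    denom = b2 * p + r + e
    f = (1.0 + b2) * p * r / denom
    value = float(np.mean(1.0 - f[present]))

    # chain rule through P(I, Sp) and R(I, Sg) per class
    df_dp = (1.0 + b2) * (r**2 + r * e) / denom**2
    df_dr = (1.0 + b2) * p * (b2 * p + e) / denom**2
    dp_di = 1.0 / (pred_mass + e)
    dp_dsp = -inter / (pred_mass + e) ** 2
    dr_di = 1.0 / (ref_mass + e)
    # dI/dpr = gt, dSp/dpr = 1; dSg/dpr = 0
    ci = np.where(present, df_dp * dp_di + df_dr * dr_di, 0.0)
    cs = np.where(present, df_dp * dp_dsp, 0.0)
    grad = -(gt * ci + cs) / max(n_def, 1)
    return value, grad


def total_loss(batch, pr=None, params: LossParams = LossParams()) -> float:
    """Combined objective: focal + Dice on the same batch and parameters."""
    gt, pr = _unpack(batch, pr)
    return focal_loss(gt, pr, params) + dice_loss(gt, pr, params)


def total_loss_grad(batch, pr=None, params: LossParams = LossParams()):
    gt, pr = _unpack(batch, pr)
    fv, fg = focal_loss_grad(gt, pr, params)
    dv, dg = dice_loss_grad(gt, pr, params)
    return fv + dv, fg + dg


#: Loss registry keyed the way the training configuration selects them.
LOSSES = {
    "focal": (focal_loss, focal_loss_grad),
    "dice": (dice_loss, dice_loss_grad),
    "focal+dice": (total_loss, total_loss_grad),
}


def get_loss(name: str):
    """Return (loss_fn, grad_fn) for a configuration key."""
    try:
        return LOSSES[name]
    except KeyError:
        raise ValueError(
            f"unknown loss {name!r}; choose from {sorted(LOSSES)}"
        ) from None
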