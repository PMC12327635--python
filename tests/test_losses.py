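"""Loss functions against an independent scalar per-pixel/per-class oracle."""

import math

import numpy as np
import pytest

from mangroveseg import LossParams, PredictionBatch, dice_loss, focal_loss, total_loss
from mangroveseg.losses import (dice_loss_grad, focal_loss_grad, get_loss,
                                total_loss_grad)

from conftest import random_probs


# --- oracles: explicit Python loops, no vectorization -----------------------

def focal_oracle(gt, pr, p: LossParams) -> float:
    gt = gt.reshape(-1, gt.shape[-1])
    pr = pr.reshape(-1, pr.shape[-1])
    total = 0.0
    for px in range(gt.shape[0]):
        for c in range(gt.shape[1]):
            total += -gt[px, c] * p.alpha * (1.0 - pr[px, c]) ** p.gamma \
                * math.log(pr[px, c] + p.epsilon)
    return total / gt.shape[0]


def dice_oracle(gt, pr, p: LossParams) -> float:
    gt = gt.reshape(-1, gt.shape[-1])
    pr = pr.reshape(-1, pr.shape[-1])
    losses = []
    for c in range(gt.shape[1]):
        inter = sp = sg = 0.0
        for px in range(gt.shape[0]):
            inter += gt[px, c] * pr[px, c]
            sp += pr[px, c]
            sg += gt[px, c]
        if sg == 0:
            continue  # class absent from ground truth: undefined, excluded
        prec = inter / (sp + p.epsilon)
        rec = inter / (sg + p.epsilon)
        b2 = p.beta**2
        losses.append(1.0 - (1.0 + b2) * prec * rec / (b2 * prec + rec + p.epsilon))
    return sum(losses) / len(losses)


def _random_batch(rng, n_classes=None, shape=None):
    c = n_classes or int(rng.integers(2, 7))
    shape = shape or (int(rng.integers(1, 4)), int(rng.integers(4, 9)),
                      int(rng.integers(4, 9)))
    gt = np.eye(c)[rng.integers(0, c, shape)]
    pr = random_probs(rng, shape, c)
    return gt, pr


def test_vectorized_matches_oracle_on_many_batches(rng):
    params = LossParams()
    for _ in range(50):
        gt, pr = _random_batch(rng)
        assert focal_loss(gt, pr, params) == pytest.approx(
            focal_oracle(gt, pr, params), abs=1e-6)
        assert dice_loss(gt, pr, params) == pytest.approx(
            dice_oracle(gt, pr, params), abs=1e-6)
        assert total_loss(gt, pr, params) == pytest.approx(
            focal_oracle(gt, pr, params) + dice_oracle(gt, pr, params), abs=1e-6)


def test_focal_direct_value():
    # single pixel, two classes, pr=0.5 on the true class:
    # 0.25 * 0.5^2 * ln 2 = 0.043321...
    gt = np.array([[1.0, 0.0]])
    pr = np.array([[0.5, 0.5]])
    expected = 0.25 * 0.25 * math.log(2.0)
    assert focal_loss(gt, pr) == pytest.approx(expected, rel=1e-4)


def test_focal_gamma0_alpha1_is_cross_entropy(rng):
    params = LossParams(alpha=1.0, gamma=0.0)
    gt, pr = _random_batch(rng, n_classes=4)
    ce = -(gt * np.log(pr + params.epsilon)).sum(axis=-1).mean()
    assert focal_loss(gt, pr, params) == pytest.approx(float(ce), abs=1e-12)


def test_perfect_prediction_gives_zero(rng):
    c = 5
    y = rng.integers(0, c, (3, 6, 6))
    gt = np.eye(c)[y]
    assert focal_loss(gt, gt.copy()) == pytest.approx(0.0, abs=1e-5)
    assert dice_loss(gt, gt.copy()) == pytest.approx(0.0, abs=1e-5)
    assert total_loss(gt, gt.copy()) == pytest.approx(0.0, abs=1e-5)


def test_dice_fbeta_form():
    # P = R = 0.5 at beta=1 gives 1 - 2*0.25/1.0 = 0.5; engineered batch:
    # 2 pixels, one class-0 reference, prediction splits mass so that
    # intersection=0.5, prediction mass=1, reference mass=1 on class 0.
    gt = np.array([[1.0, 0.0], [0.0, 1.0]])
    pr = np.array([[0.5, 0.5], [0.5, 0.5]])
    # class 0: P=0.5/1=0.5, R=0.5/1=0.5 -> 0.5 ; class 1 identical
    assert dice_loss(gt, pr) == pytest.approx(0.5, rel=1e-5)


def test_dice_beta_limit_approaches_one_minus_precision(rng):
    gt, pr = _random_batch(rng, n_classes=3)
    params_small = LossParams(beta=1e-4)
    c = gt.shape[-1]
    g2 = gt.reshape(-1, c)
    p2 = pr.reshape(-1, c)
    expected = []
    for k in range(c):
        if g2[:, k].sum() == 0:
            continue
        prec = (g2[:, k] * p2[:, k]).sum() / (p2[:, k].sum() + params_small.epsilon)
        expected.append(1.0 - prec)
    assert dice_loss(gt, pr, params_small) == pytest.approx(
        float(np.mean(expected)), abs=1e-3)


def test_total_is_sum_of_parts(rng):
    gt, pr = _random_batch(rng)
    assert total_loss(gt, pr) == pytest.approx(
        focal_loss(gt, pr) + dice_loss(gt, pr), abs=1e-10)


def test_focal_monotone_in_true_class_probability():
    # raising pr on the true class (mass taken from the other class) never
    # increases the loss
    values = []
    for p in np.linspace(0.05, 0.95, 10):
        gt = np.array([[1.0, 0.0]])
        pr = np.array([[p, 1.0 - p]])
        values.append(focal_loss(gt, pr))
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_non_negativity(rng):
    for _ in range(10):
        gt, pr = _random_batch(rng)
        assert focal_loss(gt, pr) >= 0.0
        assert 0.0 <= dice_loss(gt, pr) <= 1.0
        assert total_loss(gt, pr) >= 0.0


@pytest.mark.parametrize("grad_fn,loss_fn_name", [
    (focal_loss_grad, "focal"),
    (dice_loss_grad, "dice"),
    (total_loss_grad, "focal+dice"),
])
def test_gradients_match_finite_differences(rng, grad_fn, loss_fn_name):
    loss_fn, _ = get_loss(loss_fn_name)
    gt, pr = _random_batch(rng, n_classes=4, shape=(2, 4, 4))
    _, grad = grad_fn(gt, pr)
    eps = 1e-6
    for _ in range(15):
        idx = tuple(rng.integers(0, s) for s in pr.shape)
        up, down = pr.copy(), pr.copy()
        up[idx] += eps
        down[idx] -= eps
        fd = (loss_fn(gt, up) - loss_fn(gt, down)) / (2 * eps)
        assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


def test_prediction_batch_validation(rng):
    c = 3
    gt = np.eye(c)[rng.integers(0, c, (4, 4))]
    pr = random_probs(rng, (4, 4), c)
    PredictionBatch(gt, pr)  # valid
    with pytest.raises(ValueError):
        PredictionBatch(gt[:2], pr)  # shape mismatch
    with pytest.raises(ValueError):
        PredictionBatch(gt, pr * 2.0)  # not a distribution
    with pytest.raises(ValueError):
        PredictionBatch(pr, pr)  # gt not one-hot


def test_loss_params_validation():
    with pytest.raises(ValueError):
        LossParams(alpha=0.0)
    with pytest.raises(ValueError):
        LossParams(gamma=-1.0)
    with pytest.raises(ValueError):
        LossParams(beta=0.0)


def test_shape_mismatch_rejected(rng):
    gt = np.eye(3)[rng.integers(0, 3, (4, 4))]
    pr = random_probs(rng, (4, 5), 3)
    with pytest.raises(ValueError):
        focal_loss(gt, pr)
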