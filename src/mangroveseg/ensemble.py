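"""Weighted-averaging (soft-voting) ensemble and weight grid search.

The ensemble prediction at a pixel is the weighted sum of the member
models' class-probability vectors, P(t) = sum_i w_i p_i(t), renormalized
to a probability vector; the hard class map is its argmax. Weights are
non-negative, not forced to sum to one (renormalization absorbs the
scale), and are found by exhaustively scoring every vector on the grid
{0, step, ..., 1}^N against a held-out reference mask, maximizing macro
mean IoU by default. Because the unit vectors lie on the grid, the
searched ensemble can never score below its best single member.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import metrics
from .raster import LabelMask


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative per-member weights, at least one positive."""

    weights: tuple[float, ...]
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.member_ids):
            raise ValueError("one weight per member id required")
        if len(self.weights) == 0:
            raise ValueError("ensemble needs at least one member")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in self.weights):
            raise ValueError("at least one weight must be positive")

    def to_json(self, path: str | Path, **extra) -> None:
        Path(path).write_text(
            json.dumps(
                {"member_ids": list(self.member_ids),
                 "weights": list(self.weights), **extra},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleWeights":
        d = json.loads(Path(path).read_text())
        return cls(weights=tuple(d["weights"]), member_ids=tuple(d["member_ids"]))


@dataclass(frozen=True)
class WeightSearchResult:
    best: EnsembleWeights
    best_score: float
    objective: str
    grid_step: float
    evaluations: int

    @property
    def best_mean_iou(self) -> float:  # convenience alias for the default objective
        return self.best_score


def _stack_members(prob_maps: list[np.ndarray]) -> np.ndarray:
    maps = [np.asarray(m, dtype=np.float32) for m in prob_maps]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("all member probability maps must share shape and class count")
    if maps[0].ndim < 2:
        raise ValueError("probability maps must be (..., C)")
    return np.stack(maps)


def ensemble_predict(prob_maps: list[np.ndarray],
                     weights: EnsembleWeights | list[float]) -> np.ndarray:
    """Weighted per-pixel sum of member probabilities, renormalized to 1."""
    w = np.asarray(
        weights.weights if isinstance(weights, EnsembleWeights) else weights,
        dtype=np.float64,
    )
    if (w < 0).any() or not (w > 0).any():
        raise ValueError("weights must be non-negative with at least one positive")
    stack = _stack_members(prob_maps)
    if len(w) != len(stack):
        raise ValueError(f"{len(stack)} member maps but {len(w)} weights")
    combined = np.tensordot(w, stack, axes=1)
    return (combined / w.sum()).astype(np.float32)


_OBJECTIVES = ("mean_iou", "oa", "mean_f1")


def _score(cm_pred: np.ndarray, ref: np.ndarray, num_classes: int, objective: str) -> float:
    cm = metrics.confusion_matrix(cm_pred, ref, num_classes)
    if objective == "mean_iou":
        return metrics.per_class_iou(cm)[1]
    if objective == "oa":
        return metrics.overall_accuracy(cm)
    if objective == "mean_f1":
        return metrics.per_class_f1(cm)[1]
    raise ValueError(f"unknown objective {objective!r}; choose from {_OBJECTIVES}")


def search_weights(prob_maps: list[np.ndarray], reference: LabelMask | np.ndarray,
                   grid_step: float = 0.1, objective: str = "mean_iou",
                   member_ids: tuple[str, ...] | None = None) -> WeightSearchResult:
    """Exhaustive grid search over {0, step, ..., 1}^N, excluding all-zero.

    Scores the ensemble hard map against the held-out reference; ties break
    to the lexicographically smallest weight vector. Deterministic.
    """
    if len(prob_maps) < 2:
        raise ValueError("weight search needs at least two members")
    if not 0.0 < grid_step <= 0.5:
        raise ValueError("grid_step must lie in (0, 0.5]")
    stack = _stack_members(prob_maps)
    n_members = len(stack)
    num_classes = stack.shape[-1]
    ref = reference.classes if isinstance(reference, LabelMask) else np.asarray(reference)
    if ref.shape != stack.shape[1:-1]:
        raise ValueError(
            f"reference shape {ref.shape} does not match maps {stack.shape[1:-1]}"
        )
    levels = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    if len(levels) < 2:
        raise ValueError("grid is degenerate")
    flat = stack.reshape(n_members, -1, num_classes)
    best_w, best_score, evaluations = None, -np.inf, 0
    for w in itertools.product(levels, repeat=n_members):
        if not any(w):
            continue
        evaluations += 1
        hard = np.tensordot(np.asarray(w, dtype=np.float32), flat, axes=1).argmax(axis=-1)
        score = _score(hard, ref.ravel(), num_classes, objective)
        if score > best_score:  # first maximizer in lexicographic order wins
            best_score, best_w = score, w
    ids = member_ids or tuple(f"member_{i}" for i in range(n_members))
    return WeightSearchResult(
        best=EnsembleWeights(weights=tuple(float(v) for v in best_w), member_ids=ids),
        best_score=float(best_score),
        objective=objective,
        grid_step=grid_step,
        evaluations=evaluations,
    )
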