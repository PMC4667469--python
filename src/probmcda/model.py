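"""Deterministic multi-attribute value model.

The core of the package is an additive multi-attribute value function.
Each criterion ``k`` has a "worst imaginable" anchor level ``worst_level``
and a "best imaginable" anchor level ``best_level``.  A partial value
function maps a raw performance level ``theta`` linearly onto ``[0, 1]``
between those anchors, clamping beyond them.  Criterion weights ``w_k``
express the relative importance of a full swing from worst to best, and
the overall value of an alternative is the weighted sum of its partial
values.

Two aggregation conventions are provided:

``complement``
    Minimized criteria enter through their partial value, i.e. as
    ``1 - badness`` for 0-100% anchors.  This is the textbook additive
    model: all contributions are nonnegative and the overall value lies
    in ``[0, 1]`` for weights on the simplex.

``signed``
    Minimized criteria enter as *negatively* weighted badness (for
    0-100% anchors, the raw event proportion).  The signed score equals
    the complement score minus the constant ``sum of minimized-criterion
    weights``, so rankings under a shared weight vector are identical.
    Benefit-risk reports often quote scores on this scale, where risks
    visibly subtract from benefits; it is the package default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "Convention",
    "Criterion",
    "partial_value",
    "badness",
    "overall_value",
    "overall_values",
    "normalize_weights",
    "check_weight_vector",
]


class Direction(str, Enum):
    """Optimization direction of a criterion."""

    MAXIMIZE = "maximize"
    MINIMIZE = "minimize"


class Convention(str, Enum):
    """Aggregation convention for minimized criteria (see module docstring)."""

    COMPLEMENT = "complement"
    SIGNED = "signed"


@dataclass(frozen=True)
class Criterion:
    """A named decision criterion with direction and anchor levels.

    Parameters
    ----------
    name:
        Label used to index weights and performances.
    direction:
        Whether higher raw performance is better (``maximize``) or worse
        (``minimize``).
    worst_level, best_level:
        Anchor levels in the criterion's own units.  For a maximized
        criterion ``best_level > worst_level``; for a minimized criterion
        ``best_level < worst_level``.  In the packaged case all criteria
        are probabilities with anchors 0 and 1.
    """

    name: str
    direction: Direction
    worst_level: float
    best_level: float

    def __post_init__(self) -> None:
        direction = Direction(self.direction)
        object.__setattr__(self, "direction", direction)
        if not (np.isfinite(self.worst_level) and np.isfinite(self.best_level)):
            raise ValueError(f"criterion {self.name!r}: anchors must be finite")
        if self.worst_level == self.best_level:
            raise ValueError(f"criterion {self.name!r}: anchors must differ")
        if direction is Direction.MAXIMIZE and not self.best_level > self.worst_level:
            raise ValueError(
                f"criterion {self.name!r}: maximize requires best_level > worst_level"
            )
        if direction is Direction.MINIMIZE and not self.best_level < self.worst_level:
            raise ValueError(
                f"criterion {self.name!r}: minimize requires best_level < worst_level"
            )

    @property
    def is_minimized(self) -> bool:
        return self.direction is Direction.MINIMIZE


def _linear_clamped(theta, worst: float, best: float):
    """(theta - worst)/(best - worst), clamped to [0, 1].

    Works for both directions: for a minimized criterion the denominator
    is negative and clamping still lands on the correct side.
    """
    return np.clip((np.asarray(theta, dtype=float) - worst) / (best - worst), 0.0, 1.0)


def partial_value(theta, criterion: Criterion):
    """Partial value of raw performance ``theta`` on ``criterion``.

    Piecewise linear: 1 at or beyond the best anchor, 0 at or beyond the
    worst anchor, linear in between.  Accepts scalars or arrays; scalar
    input returns a float.  Performances beyond the anchors are clamped
    with a logged warning.

    Raises
    ------
    ValueError
        If ``theta`` contains non-finite values.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"criterion {criterion.name!r}: non-finite performance value")
    lo, hi = sorted((criterion.worst_level, criterion.best_level))
    if np.any(arr < lo) or np.any(arr > hi):
        logger.warning(
            "criterion %r: performance outside anchors [%g, %g]; clamping",
            criterion.name,
            lo,
            hi,
        )
    out = _linear_clamped(arr, criterion.worst_level, criterion.best_level)
    if np.isscalar(theta) or arr.ndim == 0:
        return float(out)
    return out


def badness(theta, criterion: Criterion):
    """Performance mapped to [0, 1] of badness: ``1 - partial_value``.

    For a minimized proportion criterion with anchors (worst=1, best=0)
    this is the raw event proportion.
    """
    return 1.0 - partial_value(theta, criterion)


def normalize_weights(weights) -> np.ndarray:
    """Explicitly rescale a nonnegative weight vector to sum to 1.

    Normalization is never applied silently elsewhere in the package;
    call this when you want it.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return w / total


def check_weight_vector(weights, tol: float = 1e-9) -> list[str]:
    """Return a list of human-readable issues with a weight vector.

    An empty list means the vector is nonnegative and sums to 1 within
    ``tol``.  Raw (non-normalized) vectors are permitted downstream but
    should be flagged to the user via these messages.
    """
    w = np.asarray(weights, dtype=float)
    issues = []
    if np.any(~np.isfinite(w)):
        issues.append("weight vector contains non-finite entries")
    if np.any(w < 0):
        issues.append("weight vector contains negative entries")
    total = float(w.sum())
    if abs(total - 1.0) > tol:
        issues.append(f"weights sum to {total:.6g}, not 1")
    return issues


def _as_aligned_array(values, criteria: Sequence[Criterion], what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != len(criteria):
        raise ValueError(
            f"{what} has {arr.shape[-1]} entries but {len(criteria)} criteria declared"
        )
    return arr


def overall_value(
    weights,
    performances,
    criteria: Sequence[Criterion],
    convention: Convention | str = Convention.SIGNED,
) -> float:
    """Overall value of one alternative: weighted sum of partial values.

    Parameters
    ----------
    weights, performances:
        Vectors aligned with ``criteria`` (the canonical declared order).
    convention:
        ``complement`` or ``signed``; see module docstring.  The two
        differ by the constant sum of minimized-criterion weights, so
        rankings are unaffected by the choice.
    """
    convention = Convention(convention)
    w = _as_aligned_array(weights, criteria, "weight vector")
    theta = _as_aligned_array(performances, criteria, "performance vector")
    if w.ndim != 1 or theta.ndim != 1:
        raise ValueError("overall_value expects 1-D weight and performance vectors")
    total = 0.0
    for wk, tk, crit in zip(w, theta, criteria):
        v = partial_value(tk, crit)
        if convention is Convention.SIGNED and crit.is_minimized:
            total -= wk * (1.0 - v)
        else:
            total += wk * v
    return float(total)


def overall_values(
    weight_draws: np.ndarray,
    performance_draws: np.ndarray,
    criteria: Sequence[Criterion],
    convention: Convention | str = Convention.SIGNED,
) -> np.ndarray:
    """Vectorized overall values for a Monte Carlo batch.

    Parameters
    ----------
    weight_draws:
        Array of shape ``(T, K)``: one weight vector per run, shared
        across alternatives within the run.
    performance_draws:
        Array of shape ``(T, I, K)``: per-run, per-alternative raw
        performances.

    Returns
    -------
    ndarray of shape ``(T, I)`` of overall values.
    """
    convention = Convention(convention)
    W = np.asarray(weight_draws, dtype=float)
    Theta = np.asarray(performance_draws, dtype=float)
    if W.ndim != 2 or Theta.ndim != 3:
        raise ValueError("expected weight_draws (T, K) and performance_draws (T, I, K)")
    if W.shape[0] != Theta.shape[0] or W.shape[1] != Theta.shape[2]:
        raise ValueError("weight and performance draw shapes are misaligned")
    if W.shape[1] != len(criteria):
        raise ValueError("draw width does not match number of criteria")
    partials = np.empty_like(Theta)
    for j, crit in enumerate(criteria):
        partials[:, :, j] = partial_value(Theta[:, :, j], crit)
    values = np.einsum("tk,tik->ti", W, partials)
    if convention is Convention.SIGNED:
        minimized = np.array([c.is_minimized for c in criteria])
        if minimized.any():
            values = values - W[:, minimized].sum(axis=1)[:, None]
    return values
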