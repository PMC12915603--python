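"""Influence curves for sequential binary choice under social influence.

An influence curve ``f`` maps the current popularity ``x`` of option A (the
share of prior adopters that chose A) to the probability that the next
individual chooses A.  Curves are nondecreasing, take values in [0, 1], and may
have a single discontinuity at ``x = 1/2``: the *marginal majority effect* M.
Every curve decomposes as

    f(x) = g(x) + (M / 2) * u(x),

with ``g`` continuous at 1/2 and ``u(x) = sign(x - 1/2)`` (``u(1/2) = 0``), so
``f(1/2) = g(1/2)``.  The *inherent appeal difference* between the two options
is ``d = 1 - 2 g(1/2)``; by the convention that A is the inherently less
appealing option, ``d >= 0``.  Since ``f >= 0`` near 1/2, feasible parameters
satisfy ``M + d <= 1``.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CurveError, EstimationError

__all__ = [
    "InfluenceCurve",
    "StepCurve",
    "LogisticCurve",
    "PiecewiseConstantCurve",
    "MixtureCurve",
    "Decomposition",
    "evaluate_curve",
    "decompose_curve",
    "check_feasibility",
    "aggregate_curves",
    "curve_from_config",
]

_GRID = np.linspace(0.0, 1.0, 1001)
_MONOTONE_TOL = 1e-12


class InfluenceCurve(abc.ABC):
    """Abstract nondecreasing map from popularity in [0, 1] to choice probability."""

    @abc.abstractmethod
    def _value(self, x: np.ndarray) -> np.ndarray:
        """Vectorised evaluation; ``x`` is a float array inside [0, 1]."""

    def __call__(self, x):
        arr = np.asarray(x, dtype=float)
        if np.any(np.isnan(arr)) or np.any((arr < 0.0) | (arr > 1.0)):
            raise CurveError(f"popularity must lie in [0, 1], got {x!r}")
        out = np.asarray(self._value(np.atleast_1d(arr)), dtype=float)
        if arr.ndim == 0:
            return float(out[0])
        return out.reshape(arr.shape)

    # -- one-sided limits at x = 1/2 ------------------------------------
    # Subclasses with closed forms override these; the generic fallback
    # approaches 1/2 along a geometric offset sequence eps, eps/2, ... and
    # returns the last value (no extrapolation).

    def left_limit(self, eps: float = 1e-4) -> float:
        return self._numeric_limit(side=-1, eps=eps)

    def right_limit(self, eps: float = 1e-4) -> float:
        return self._numeric_limit(side=+1, eps=eps)

    def _numeric_limit(self, side: int, eps: float) -> float:
        if eps <= 0:
            raise CurveError("eps must be positive")
        offsets = eps * 0.5 ** np.arange(16)
        vals = self(0.5 + side * offsets)
        # for a nondecreasing f the sequence must approach the limit monotonically
        diffs = np.diff(vals) * side
        if np.any(diffs > 1e-9):
            raise EstimationError("non-monotone limit sequence at x = 1/2")
        return float(vals[-1])

    @property
    def jump(self) -> float:
        """Size of the discontinuity at x = 1/2 (the marginal majority effect M)."""
        return self.right_limit() - self.left_limit()

    def validate(self) -> None:
        """Check range and monotonicity on a 1001-point grid; raise CurveError."""
        vals = self(_GRID)
        if np.any(vals < -_MONOTONE_TOL) or np.any(vals > 1.0 + _MONOTONE_TOL):
            raise CurveError("curve takes values outside [0, 1]")
        if np.any(np.diff(vals) < -_MONOTONE_TOL):
            raise CurveError("curve is not nondecreasing")


@dataclass(frozen=True)
class StepCurve(InfluenceCurve):
    """Two flat levels on either side of x = 1/2: pure majority-based influence.

    ``mid`` is the value at exactly 1/2 and defaults to ``(low + high) / 2``,
    i.e. the u(1/2) = 0 convention, so that f(1/2) = g(1/2).
    """

    low: float
    high: float
    mid: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise CurveError(f"need 0 <= low <= high <= 1, got ({self.low}, {self.high})")
        mid = (self.low + self.high) / 2.0 if self.mid is None else float(self.mid)
        if not (self.low <= mid <= self.high):
            raise CurveError(f"mid value {mid} outside [low, high]")
        object.__setattr__(self, "mid", mid)

    def _value(self, x):
        return np.where(x < 0.5, self.low, np.where(x > 0.5, self.high, self.mid))

    def left_limit(self, eps: float = 1e-4) -> float:
        return self.low

    def right_limit(self, eps: float = 1e-4) -> float:
        return self.high

    @classmethod
    def from_md(cls, M: float, d: float) -> "StepCurve":
        """Flat curve with marginal majority effect ``M`` and appeal difference ``d``.

        Levels are ``(1 - d -/+ M) / 2``, i.e. g is the constant ``(1 - d) / 2``.
        """
        if not check_feasibility(M, d):
            raise CurveError(f"infeasible (M, d) = ({M}, {d})")
        return cls((1.0 - d - M) / 2.0, (1.0 - d + M) / 2.0)


@dataclass(frozen=True)
class LogisticCurve(InfluenceCurve):
    """Continuous logistic influence curve

        f(x) = 1 / (1 + ((1 + d) / (1 - d)) * exp(b * (1 - 2 x))),

    the standard binary-choice form: ``d`` in [0, 1) is the inherent appeal
    difference (f(1/2) = (1 - d) / 2) and ``b >= 0`` controls the strength of
    social influence (the slope).
    """

    d: float
    b: float

    def __post_init__(self):
        if not (0.0 <= self.d < 1.0):
            raise CurveError(f"d must be in [0, 1), got {self.d}")
        if self.b < 0:
            raise CurveError(f"b must be >= 0, got {self.b}")

    def _value(self, x):
        ratio = (1.0 + self.d) / (1.0 - self.d)
        return 1.0 / (1.0 + ratio * np.exp(self.b * (1.0 - 2.0 * x)))

    def left_limit(self, eps: float = 1e-4) -> float:
        return (1.0 - self.d) / 2.0

    def right_limit(self, eps: float = 1e-4) -> float:
        return (1.0 - self.d) / 2.0


@dataclass(frozen=True)
class PiecewiseConstantCurve(InfluenceCurve):
    """Step function on a partition of [0, 1]; carrier for binned empirical curves.

    Bins are half-open ``[e_i, e_{i+1})`` (last bin closed).  If 1/2 is an
    interior edge, the value at exactly 1/2 is the mean of the two adjacent bin
    values (the u(1/2) = 0 convention).
    """

    edges: tuple
    values: tuple

    def __init__(self, edges: Sequence[float], values: Sequence[float]):
        edges = tuple(float(e) for e in edges)
        values = tuple(float(v) for v in values)
        if len(edges) != len(values) + 1:
            raise CurveError("need exactly one value per bin")
        if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
            raise CurveError("edges must strictly increase from 0 to 1")
        if np.any(np.diff(values) < -_MONOTONE_TOL):
            raise CurveError("bin values must be nondecreasing")
        if np.any((np.asarray(values) < 0) | (np.asarray(values) > 1)):
            raise CurveError("bin values must lie in [0, 1]")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "values", values)

    def _bin_index(self, x):
        idx = np.searchsorted(self.edges, x, side="right") - 1
        return np.clip(idx, 0, len(self.values) - 1)

    def _value(self, x):
        vals = np.asarray(self.values)[self._bin_index(x)]
        if 0.5 in self.edges[1:-1]:
            i = self.edges.index(0.5)
            mid = (self.values[i - 1] + self.values[i]) / 2.0
            vals = np.where(x == 0.5, mid, vals)
        return vals

    def left_limit(self, eps: float = 1e-4) -> float:
        idx = int(np.searchsorted(self.edges, 0.5, side="left")) - 1
        return self.values[max(idx, 0)]

    def right_limit(self, eps: float = 1e-4) -> float:
        idx = int(np.searchsorted(self.edges, 0.5, side="right")) - 1
        return self.values[min(idx, len(self.values) - 1)]


@dataclass(frozen=True)
class MixtureCurve(InfluenceCurve):
    """Population mixture: weighted average of individual-level influence curves.

    One-sided limits (hence the jump M) are the weighted averages of the
    component limits, so averaging can only smooth a curve, never steepen it.
    """

    components: tuple
    weights: tuple

    def __init__(self, components: Sequence[InfluenceCurve], weights: Sequence[float]):
        components = tuple(components)
        weights = tuple(float(w) for w in weights)
        if len(components) == 0:
            raise CurveError("mixture needs at least one component")
        if len(components) != len(weights):
            raise CurveError("components and weights must have equal length")
        if any(w < 0 for w in weights):
            raise CurveError("weights must be nonnegative")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise CurveError(f"weights must sum to 1, got {sum(weights)}")
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "weights", weights)

    def _value(self, x):
        out = np.zeros_like(x, dtype=float)
        for w, c in zip(self.weights, self.components):
            out += w * c._value(x)
        return out

    def left_limit(self, eps: float = 1e-4) -> float:
        return float(sum(w * c.left_limit(eps) for w, c in zip(self.weights, self.components)))

    def right_limit(self, eps: float = 1e-4) -> float:
        return float(sum(w * c.right_limit(eps) for w, c in zip(self.weights, self.components)))


@dataclass(frozen=True)
class Decomposition:
    """f(x) = g(x) + (M/2) u(x) summarised at x = 1/2.

    Attributes
    ----------
    M : jump of f at 1/2 (marginal majority effect), >= 0.
    d : inherent appeal difference, 1 - 2 g(1/2).
    g_half : value of the continuous part at 1/2 (= f(1/2) under u(1/2) = 0).
    left_limit, right_limit : one-sided limits of f at 1/2.
    c : right limit, g(1/2) + M/2 — the choice probability floor just above 1/2.
    """

    M: float
    d: float
    g_half: float
    left_limit: float
    right_limit: float
    c: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "c", self.g_half + self.M / 2.0)


def evaluate_curve(curve: InfluenceCurve, x) -> float:
    """Evaluate ``curve`` at popularity ``x`` (scalar or array) in [0, 1]."""
    return curve(x)


def decompose_curve(curve: InfluenceCurve, eps: float = 1e-4) -> Decomposition:
    """Split ``curve`` into its continuous part and the jump at 1/2.

    Uses the curve's one-sided limits (closed-form for the built-in families,
    a geometric offset sequence otherwise, controlled by ``eps``).
    """
    left = curve.left_limit(eps)
    right = curve.right_limit(eps)
    M = right - left
    if M < -1e-9:
        raise EstimationError("negative jump: curve is not nondecreasing at 1/2")
    M = max(M, 0.0)
    g_half = (left + right) / 2.0
    return Decomposition(M=M, d=1.0 - 2.0 * g_half, g_half=g_half,
                         left_limit=left, right_limit=right)


def check_feasibility(M: float, d: float) -> bool:
    """True iff (M, d) is a feasible parameter pair: M >= 0, d >= 0, M + d <= 1.

    d >= 0 encodes the convention that A is the inherently less appealing
    option (f(1/2) <= 1/2); M + d <= 1 follows from f >= 0 near 1/2.
    """
    return bool(M >= 0.0 and d >= 0.0 and M + d <= 1.0)


def aggregate_curves(curves: Sequence[InfluenceCurve],
                     weights: Sequence[float]) -> MixtureCurve:
    """Aggregate individual-level curves into the population curve.

    The mixture evaluates to the weighted mean of component values, and its
    marginal majority effect is the weighted mean of component jumps.
    """
    return MixtureCurve(curves, weights)


_CURVE_TYPES = {"step", "logistic", "piecewise", "mixture"}


def curve_from_config(config: dict) -> InfluenceCurve:
    """Build a curve from a JSON-style dict: {"type": ..., parameters...}.

    Recognised forms::

        {"type": "step", "low": .., "high": .., "mid": ..?}
        {"type": "logistic", "d": .., "b": ..}
        {"type": "piecewise", "edges": [..], "values": [..]}
        {"type": "mixture", "components": [..configs..], "weights": [..]}
    """
    if "type" not in config:
        raise CurveError("curve config needs a 'type' field")
    kind = config["type"]
    if kind == "step":
        return StepCurve(config["low"], config["high"], config.get("mid"))
    if kind == "logistic":
        return LogisticCurve(d=config["d"], b=config["b"])
    if kind == "piecewise":
        return PiecewiseConstantCurve(config["edges"], config["values"])
    if kind == "mixture":
        comps = [curve_from_config(c) for c in config["components"]]
        return MixtureCurve(comps, config["weights"])
    raise CurveError(f"unknown curve type {kind!r}; expected one of {sorted(_CURVE_TYPES)}")
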