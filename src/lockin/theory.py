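"""Closed-form lock-in criteria and probability bounds.

Main results implemented here, for a feasible parameter pair (M, d):

* M > d guarantees that the process is lock-in-prone (the curve enters the
  lock-in region immediately to the right of x = 1/2), and M > 0.5 alone
  suffices since M + d <= 1 then forces d < 0.5.
* When M > d, the lock-in probability p_L = P(x_inf > 1/2) satisfies

      p_L >= 2 (M - d)(1 - d) / [ (1 - d)(1 - d + M) + 2 M ].

  The bound is the survival probability of a nearest-neighbour random walk on
  the integers with up-step probability q0 = (1 - d)/2 at state 0 and
  q+ = (1 - d + M)/2 at positive states: the walk is the count difference
  2*Y_n - n of an auxiliary step process that minorises the original one, and
  survival (never going negative) keeps the popularity at or above 1/2 forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import check_feasibility

__all__ = [
    "CriterionReport",
    "WalkParams",
    "BoundReport",
    "mm_criterion",
    "lock_in_probability_bound",
    "walk_survival_probability",
    "never_return_probability",
    "zero_lock_in_probability",
    "mc_walk_survival",
]


@dataclass(frozen=True)
class CriterionReport:
    """Outcome of the marginal-majority lock-in criteria for one (M, d) pair."""

    M: float
    d: float
    feasible: bool
    mm_condition: bool       # M > d
    corollary: bool          # M > 0.5
    lock_in_guaranteed: bool


@dataclass(frozen=True)
class WalkParams:
    """Nearest-neighbour walk on Z: up-step probability q0 at state 0, q_plus above."""

    q0: float
    q_plus: float

    def __post_init__(self):
        if not (0.0 <= self.q0 <= 1.0 and 0.0 <= self.q_plus <= 1.0):
            raise ValueError("step probabilities must lie in [0, 1]")

    @classmethod
    def from_md(cls, M: float, d: float) -> "WalkParams":
        """Parameter mapping from the auxiliary step process: q+ = (1-d+M)/2, q0 = (1-d)/2."""
        if not check_feasibility(M, d):
            raise ValueError(f"infeasible (M, d) = ({M}, {d})")
        return cls(q0=(1.0 - d) / 2.0, q_plus=(1.0 - d + M) / 2.0)


@dataclass(frozen=True)
class BoundReport:
    """Lower bound on the lock-in probability and the walk quantities behind it."""

    M: float
    d: float
    q0: float
    q_plus: float
    p_L_lower: float
    never_return_p1: float


def mm_criterion(M: float, d: float) -> CriterionReport:
    """Evaluate the lock-in criteria M > d and M > 0.5 for a feasible pair."""
    if not check_feasibility(M, d):
        raise ValueError(f"infeasible parameters (M, d) = ({M}, {d}): "
                         "need M >= 0, d >= 0, M + d <= 1")
    mm = M > d
    return CriterionReport(M=M, d=d, feasible=True, mm_condition=mm,
                           corollary=M > 0.5, lock_in_guaranteed=mm)


def lock_in_probability_bound(M: float, d: float) -> BoundReport:
    """Closed-form lower bound on P(x_inf > 1/2) when M > d.

    Raises ValueError when M <= d: the theory asserts nothing there, and a
    silent zero would invite misreading the bound as an estimate.
    """
    if not check_feasibility(M, d):
        raise ValueError(f"infeasible parameters (M, d) = ({M}, {d})")
    if M <= d:
        raise ValueError("the bound requires M > d; no bound is asserted otherwise")
    p = 2.0 * (M - d) * (1.0 - d) / ((1.0 - d) * (1.0 - d + M) + 2.0 * M)
    w = WalkParams.from_md(M, d)
    return BoundReport(M=M, d=d, q0=w.q0, q_plus=w.q_plus, p_L_lower=p,
                       never_return_p1=never_return_probability(w.q_plus))


def never_return_probability(q_plus: float) -> float:
    """P(a homogeneous walk with up-step probability q_plus > 1/2, started at 1,
    never visits 0) = (2 q+ - 1) / q+."""
    if q_plus <= 0.5:
        raise ValueError("need q_plus > 0.5 (rightward drift)")
    return (2.0 * q_plus - 1.0) / q_plus


def walk_survival_probability(params: WalkParams) -> float:
    """P(the walk started at 0 stays >= 0 forever) = q0 (2 q+ - 1) / (q+ - q0 (1 - q+))."""
    q0, qp = params.q0, params.q_plus
    if qp <= 0.5:
        raise ValueError("need q_plus > 0.5 (rightward drift) for positive survival")
    return q0 * (2.0 * qp - 1.0) / (qp - q0 * (1.0 - qp))


def zero_lock_in_probability(p_L: float, k: int) -> float:
    """Probability of observing no lock-in in k independent trials, (1 - p_L)^k."""
    if not (0.0 <= p_L <= 1.0):
        raise ValueError("p_L must be a probability")
    if k < 0:
        raise ValueError("k must be >= 0")
    return (1.0 - p_L) ** k


def mc_walk_survival(params: WalkParams, horizon: int = 10_000,
                     reps: int = 100_000, seed=None) -> tuple[float, float]:
    """Monte-Carlo estimate of the walk survival probability (brute-force oracle).

    Simulates ``reps`` independent walks for ``horizon`` steps and returns the
    fraction that never went below 0, with its binomial standard error.  Walks
    that die are dropped from the state vector, so the cost is dominated by the
    first few hundred steps.  Truncating "for all n" at a finite horizon biases
    the estimate upward by an exponentially small amount when q_plus > 1/2.
    """
    if horizon < 1_000 or reps < 1_000:
        raise ValueError("need horizon >= 1000 and reps >= 1000")
    rng = np.random.default_rng(seed)
    state = np.zeros(reps, dtype=np.int64)
    for _ in range(horizon):
        p = np.where(state > 0, params.q_plus, params.q0)
        up = rng.random(state.size) < p
        state += np.where(up, 1, -1)
        if state.size and state.min() < 0:
            state = state[state >= 0]
        if state.size == 0:
            break
    est = state.size / reps
    se = float(np.sqrt(est * (1.0 - est) / reps))
    return est, se
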