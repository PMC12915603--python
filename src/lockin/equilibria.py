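"""Equilibria of influence curves and the lock-in region test.

An equilibrium is a popularity x* where the curve meets the diagonal
(f(x*) = x*).  Where the curve crosses the diagonal from above (a
*downcrossing*) the equilibrium is stable — these are the possible long-run
popularities of the process; upcrossings are unstable and act as the critical
mass separating the basins.  The process is lock-in-prone iff the curve enters
the lock-in region {(x, y): y > x > 1/2}, equivalently iff it has a stable
equilibrium above 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .curves import InfluenceCurve, LogisticCurve, StepCurve
from .errors import UndeterminedError

__all__ = [
    "Equilibrium",
    "EquilibriumReport",
    "find_equilibria",
    "enters_lock_in_region",
    "logistic_lock_in_threshold",
]

_HALF_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    location: float
    stability: str  # 'stable' | 'unstable' | 'indeterminate'


@dataclass(frozen=True)
class EquilibriumReport:
    equilibria: tuple
    lock_in_prone: bool
    critical_mass: float | None

    @property
    def stable(self) -> tuple:
        return tuple(e for e in self.equilibria if e.stability == "stable")

    @property
    def unstable(self) -> tuple:
        return tuple(e for e in self.equilibria if e.stability == "unstable")


def _bisect_sign_change(h, lo, hi, tol):
    """Bisect a sign change of h on [lo, hi]; works across jump discontinuities,
    converging to the jump location."""
    flo = h(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = h(mid)
        if fm == 0.0:
            return mid
        if (flo > 0) == (fm > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_equilibria(curve: InfluenceCurve, grid_n: int = 2001,
                    tol: float = 1e-9, margin: float = 1e-6) -> EquilibriumReport:
    """Locate diagonal crossings of ``curve`` and classify their stability.

    Sign changes of f(x) - x on a ``grid_n``-point grid are refined by
    bisection to ``tol``; a jump-crossing at 1/2 is found the same way (the
    bisection converges to the discontinuity).  Stability is read off the sign
    pattern on the two sides.  Near-tangencies — grid points where |f(x) - x|
    dips below ``margin`` without a sign change — are reported as
    'indeterminate' rather than silently classified.
    """
    if grid_n < 100:
        raise ValueError("grid_n must be >= 100")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    xs = np.linspace(0.0, 1.0, grid_n)
    h = np.asarray(curve(xs)) - xs
    hfun = lambda x: float(curve(x)) - x

    eqs: list[Equilibrium] = []

    def classify(left_sign: float, right_sign: float) -> str:
        if left_sign > 0 and right_sign < 0:
            return "stable"
        if left_sign < 0 and right_sign > 0:
            return "unstable"
        return "indeterminate"

    # exact zeros at grid points
    zero_idx = np.where(h == 0.0)[0]
    for i in zero_idx:
        ls = h[i - 1] if i > 0 else -1.0   # f(0) > 0 implies h(0) > 0; boundary fallback
        rs = h[i + 1] if i < grid_n - 1 else 1.0
        eqs.append(Equilibrium(location=float(xs[i]), stability=classify(ls, rs)))

    # strict sign changes between grid points
    change_idx = np.where(h[:-1] * h[1:] < 0.0)[0]
    for i in change_idx:
        root = _bisect_sign_change(hfun, xs[i], xs[i + 1], tol)
        eqs.append(Equilibrium(location=float(root),
                               stability=classify(h[i], h[i + 1])))

    # near-tangencies: local extrema of h approaching 0 without a sign change
    interior = np.arange(1, grid_n - 1)
    local_max = interior[(h[interior] >= h[interior - 1]) & (h[interior] >= h[interior + 1])
                         & (h[interior] < 0) & (h[interior] > -margin)]
    local_min = interior[(h[interior] <= h[interior - 1]) & (h[interior] <= h[interior + 1])
                         & (h[interior] > 0) & (h[interior] < margin)]
    for i in np.concatenate([local_max, local_min]):
        eqs.append(Equilibrium(location=float(xs[i]), stability="indeterminate"))

    eqs.sort(key=lambda e: e.location)
    stable_locs = [e.location for e in eqs if e.stability == "stable"]
    lock_in = any(loc > 0.5 + _HALF_TOL for loc in stable_locs)
    critical = None
    if lock_in:
        top = max(stable_locs)
        below = [e.location for e in eqs
                 if e.stability == "unstable" and e.location < top]
        critical = max(below) if below else None
    return EquilibriumReport(equilibria=tuple(eqs), lock_in_prone=lock_in,
                             critical_mass=critical)


def _max_excess_above_half(curve: InfluenceCurve) -> float:
    """max over x in (1/2, 1) of f(x) - x, combining a grid scan with a local refine."""
    xs = np.linspace(0.5 + 1e-9, 1.0 - 1e-12, 2001)
    h = np.asarray(curve(xs)) - xs
    i = int(np.argmax(h))
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, xs.size - 1)]
    res = minimize_scalar(lambda x: x - float(curve(x)), bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-12})
    best = max(float(h[i]), -float(res.fun))
    # the right limit at 1/2 bounds f from below just above 1/2
    return max(best, curve.right_limit() - 0.5 - 1e-12)


def enters_lock_in_region(curve_or_binned, grid_n: int = 2001) -> bool:
    """True iff there is some x > 1/2 with f(x) > x (the curve enters {y > x > 1/2}).

    Accepts an :class:`InfluenceCurve` (analytic for step curves, grid scan plus
    the one-sided limit at 1/2 otherwise) or a binned empirical curve, which is
    assessed at bin midpoints: some bin with midpoint above 1/2 must have its
    estimate above the midpoint.  A binned curve with no data above 1/2 raises
    :class:`UndeterminedError`.
    """
    obj = curve_or_binned
    if isinstance(obj, StepCurve):
        return obj.high > 0.5
    if isinstance(obj, InfluenceCurve):
        return _max_excess_above_half(obj) > 0.0
    # binned empirical curve (duck-typed to avoid importing estimation here)
    edges = np.asarray(obj.edges, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    ests = np.asarray(obj.estimates, dtype=float)
    counts = np.asarray(obj.counts, dtype=float)
    upper = (mids > 0.5 + _HALF_TOL) & (counts > 0)
    if not upper.any():
        raise UndeterminedError("no data above popularity 1/2; lock-in region "
                                "entry is undetermined")
    return bool(np.any(ests[upper] > mids[upper]))


def logistic_lock_in_threshold(d: float, tol: float = 1e-6) -> float:
    """Smallest slope b* for which the logistic curve with appeal difference d
    enters the lock-in region.

    At the threshold the curve is tangent to the diagonal above 1/2
    (f(x) = x with f'(x) = 2 b f (1 - f) = 2 b x (1 - x) = 1); b* is found by
    bisection on whether max_{x > 1/2} (f(x) - x) is positive.  For d = 0 the
    threshold is exactly 2 (slope at the fixed point 1/2 is b/2).
    """
    if not (0.0 <= d < 1.0):
        raise ValueError("d must be in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    def entered(b: float) -> bool:
        return _max_excess_above_half(LogisticCurve(d=d, b=b)) > 0.0

    lo, hi = 0.0, 8.0
    while not entered(hi):
        lo, hi = hi, hi * 2.0
        if hi > 1e6:
            raise RuntimeError("no lock-in threshold found below b = 1e6")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if entered(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
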