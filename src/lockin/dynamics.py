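"""Seeded simulator for the sequential binary choice process (generalized urn).

Participant t observes the current popularity of option A,

    x_t = (init_a + #A among the first t-1 choices) / (init_a + init_b + t - 1),

and chooses A with probability f(x_t), where f is an influence curve.  The
initial counts (init_a, init_b) play the role of artificial seed counts (e.g.
a planted popularity advantage of about 110 to 10); with the default (1, 1)
the first participant sees popularity 1/2 and the flat step process coincides
exactly with the nearest-neighbour walk behind the lock-in probability bound
(popularity >= 1/2 iff walk state >= 0).

A party-signal variant is also provided: each participant belongs to one of
two groups and only observes *which* group currently shows larger support for
a statement, not by how much.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import InfluenceCurve
from .errors import LockinError

__all__ = [
    "ProcessSpec",
    "Trajectory",
    "EnsembleResult",
    "PartySpec",
    "PartyTrajectory",
    "simulate_trial",
    "simulate_ensemble",
    "simulate_party_trial",
    "simulate_party_ensemble",
    "party_spec_from_md",
    "end_of_trial_lock_in",
]


@dataclass(frozen=True)
class ProcessSpec:
    """Configuration of one binary choice process."""

    curve: InfluenceCurve
    horizon: int
    init_a: int = 1
    init_b: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.init_a < 0 or self.init_b < 0 or self.init_a + self.init_b < 1:
            raise ValueError("need init_a, init_b >= 0 with init_a + init_b >= 1")


@dataclass(frozen=True)
class Trajectory:
    """One realisation: per-participant choices and the popularity they observed."""

    chose_a: np.ndarray          # bool, length horizon
    popularity: np.ndarray       # x_t observed by participant t
    init_a: int
    init_b: int

    @property
    def horizon(self) -> int:
        return self.chose_a.size

    @property
    def n_a(self) -> int:
        return int(self.chose_a.sum())

    @property
    def end_popularity(self) -> float:
        """Popularity of A including all choices (and the initial counts)."""
        return (self.init_a + self.n_a) / (self.init_a + self.init_b + self.horizon)

    @property
    def choice_share(self) -> float:
        """Share of actual participants that chose A (initial counts excluded)."""
        return self.n_a / self.horizon

    @property
    def always_majority(self) -> bool:
        """True iff the observed popularity never dropped below 1/2 (end included)."""
        return bool(np.all(self.popularity >= 0.5)) and self.end_popularity >= 0.5


@dataclass(frozen=True)
class EnsembleResult:
    """Summary of independent trials of the same process."""

    end_popularities: np.ndarray
    always_majority_count: int
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return self.end_popularities.size

    @property
    def lock_in_count(self) -> int:
        return int(np.sum(self.end_popularities > 0.5))

    @property
    def lock_in_flag(self) -> bool:
        return self.lock_in_count >= 1


def _simulate_paths(curve, init_a, init_b, horizon, n_trials, rng,
                    record=False):
    """Lockstep simulation of n_trials independent trials.

    Returns (a_counts, always_majority mask, choices or None, popularity or None).
    """
    a = np.zeros(n_trials, dtype=np.int64)
    total0 = init_a + init_b
    ok = np.ones(n_trials, dtype=bool)
    choices = np.empty((horizon, n_trials), dtype=bool) if record else None
    pops = np.empty((horizon, n_trials), dtype=float) if record else None
    for t in range(1, horizon + 1):
        x = (init_a + a) / (total0 + t - 1)
        p = np.asarray(curve(x), dtype=float)
        chose = rng.random(n_trials) < p
        if record:
            choices[t - 1] = chose
            pops[t - 1] = x
        ok &= x >= 0.5
        a += chose
    end = (init_a + a) / (total0 + horizon)
    ok &= end >= 0.5
    return a, ok, choices, pops


def simulate_trial(spec: ProcessSpec) -> Trajectory:
    """Simulate a single trial; identical seeds give identical trajectories."""
    rng = np.random.default_rng(spec.seed)
    _, _, choices, pops = _simulate_paths(
        spec.curve, spec.init_a, spec.init_b, spec.horizon, 1, rng, record=True)
    return Trajectory(chose_a=choices[:, 0].copy(), popularity=pops[:, 0].copy(),
                      init_a=spec.init_a, init_b=spec.init_b)


def simulate_ensemble(spec: ProcessSpec, n_trials: int,
                      seed: int | None = None) -> EnsembleResult:
    """Simulate ``n_trials`` independent trials of ``spec``.

    Trials are advanced in lockstep (one vector of uniforms per participant
    index) from a single generator seeded by ``seed`` (falling back to
    ``spec.seed``), which makes the whole ensemble reproducible.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    use_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    a, ok, _, _ = _simulate_paths(
        spec.curve, spec.init_a, spec.init_b, spec.horizon, n_trials, rng)
    end = (spec.init_a + a) / (spec.init_a + spec.init_b + spec.horizon)
    return EnsembleResult(end_popularities=end, always_majority_count=int(ok.sum()),
                          seed=use_seed)


# ---------------------------------------------------------------------------
# Party-signal variant: participants only see which party's support leads.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartySpec:
    """Sign-only popularity signal process with two parties A and B.

    ``p_plus_P`` / ``p_minus_P`` is the probability that a party-P participant
    supports the statement when party-A support leads / trails (x > 0 / x < 0,
    where x = x_A - x_B is the difference of the running within-party support
    shares).  When x = 0 or either party has no prior participants, the
    default tie rule uses the mean of the two signal-conditional probabilities
    (mirroring u(0) = 0).
    """

    p_plus_a: float
    p_minus_a: float
    p_plus_b: float
    p_minus_b: float
    horizon: int
    assignment: str = "alternating"   # or "random" (fair coin per participant)
    tie_rule: str = "mean"
    seed: int | None = None

    def __post_init__(self):
        for name in ("p_plus_a", "p_minus_a", "p_plus_b", "p_minus_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.assignment not in ("alternating", "random"):
            raise ValueError("assignment must be 'alternating' or 'random'")
        if self.tie_rule != "mean":
            raise ValueError("only the 'mean' tie rule is implemented")


@dataclass(frozen=True)
class PartyTrajectory:
    """One realisation of the party-signal process."""

    party: np.ndarray     # 'A'/'B' per participant
    support: np.ndarray   # bool per participant
    x: np.ndarray         # x_A - x_B observed (NaN while undefined)

    @property
    def end_y(self) -> float:
        """End-of-trial support difference ybar = ybar_A - ybar_B."""
        a = self.party == "A"
        b = ~a
        ya = self.support[a].mean() if a.any() else np.nan
        yb = self.support[b].mean() if b.any() else np.nan
        return float(ya - yb)


def party_spec_from_md(M: float, d: float, horizon: int,
                       assignment: str = "alternating",
                       seed: int | None = None) -> PartySpec:
    """Symmetric party parameters realising marginal majority effect M and
    ideological content d: M_A = M, M_B = -M, baseline g_A(0) = (1 - d)/2."""
    return PartySpec(
        p_plus_a=(1.0 - d + M) / 2.0,
        p_minus_a=(1.0 - d - M) / 2.0,
        p_plus_b=(1.0 + d - M) / 2.0,
        p_minus_b=(1.0 + d + M) / 2.0,
        horizon=horizon, assignment=assignment, seed=seed)


def simulate_party_trial(spec: PartySpec) -> PartyTrajectory:
    """Simulate one trial of the sign-only party process."""
    rng = np.random.default_rng(spec.seed)
    n = spec.horizon
    if spec.assignment == "alternating":
        party_a = np.arange(n) % 2 == 0
    else:
        party_a = rng.random(n) < 0.5
    support = np.zeros(n, dtype=bool)
    xs = np.full(n, np.nan)
    cnt = {"A": 0, "B": 0}
    sup = {"A": 0, "B": 0}
    probs = {("A", +1): spec.p_plus_a, ("A", -1): spec.p_minus_a,
             ("B", +1): spec.p_plus_b, ("B", -1): spec.p_minus_b}
    for t in range(n):
        pty = "A" if party_a[t] else "B"
        if cnt["A"] > 0 and cnt["B"] > 0:
            x = sup["A"] / cnt["A"] - sup["B"] / cnt["B"]
            xs[t] = x
        else:
            x = 0.0
        if x > 0:
            p = probs[(pty, +1)]
        elif x < 0:
            p = probs[(pty, -1)]
        else:
            p = 0.5 * (probs[(pty, +1)] + probs[(pty, -1)])
        s = rng.random() < p
        support[t] = s
        cnt[pty] += 1
        sup[pty] += int(s)
    return PartyTrajectory(party=np.where(party_a, "A", "B"), support=support, x=xs)


def simulate_party_ensemble(spec: PartySpec, n_trials: int,
                            seed: int | None = None) -> np.ndarray:
    """End-of-trial support differences for n_trials independent party trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    use_seed = spec.seed if seed is None else seed
    children = np.random.SeedSequence(use_seed).spawn(n_trials)
    ends = np.empty(n_trials)
    for i, child in enumerate(children):
        sub = PartySpec(spec.p_plus_a, spec.p_minus_a, spec.p_plus_b,
                        spec.p_minus_b, spec.horizon, spec.assignment,
                        spec.tie_rule, seed=child)
        ends[i] = simulate_party_trial(sub).end_y
    return ends


def end_of_trial_lock_in(end_values, threshold: float = 0.5) -> tuple[bool, int]:
    """Lock-in flag and count from end-of-trial values (strict inequality).

    Pass an :class:`EnsembleResult` or an array of end popularities with
    ``threshold=0.5``, or party end differences with ``threshold=0.0``.
    Exact ties never count as lock-in.
    """
    if isinstance(end_values, EnsembleResult):
        vals = end_values.end_popularities
    else:
        vals = np.asarray(end_values, dtype=float)
    if vals.size == 0:
        raise LockinError("empty ensemble: lock-in is undefined")
    count = int(np.sum(vals > threshold))
    return count >= 1, count
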