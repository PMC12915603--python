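"""Synthetic multiple-world experiments and choice-table I/O.

The generator emulates the three study designs the estimation pipeline is
built for:

* ``v2019_like``  — 7 items, 2 worlds each (one seeded with an artificial
  initial advantage of about 110 to 10 for the less appealing option),
  530 and 3500 participants;
* ``mdrt2019_like`` — 20 statements, 8 worlds of 230 participants with a
  sign-only party signal, plus control worlds;
* ``fv2021_like`` — 30 questions, 10-15 worlds of 100 participants.

Ground truth per item is a flat step curve with known marginal majority
effect M and appeal difference d (drawn from feasible ranges or supplied
explicitly), so estimator recovery can be checked against the generator's
decomposition exactly.  Control records are Bernoulli draws with
p_A = g(1/2) = (1 - d)/2, the no-social-influence choice probability.

Tables are written as UTF-8 comma-separated files with a mandatory header
(item_id, world_id, t, choice, condition[, party]) and a JSON sidecar holding
the per-world artificial initial counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import StepCurve, check_feasibility, decompose_curve
from .dynamics import (ProcessSpec, simulate_ensemble, _simulate_paths,
                       party_spec_from_md, simulate_party_trial, PartySpec)
from .estimation import ChoiceTable, REQUIRED_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDesign",
    "Fixture",
    "generate_experiment",
    "v2019_like",
    "mdrt2019_like",
    "fv2021_like",
    "write_choice_table",
    "read_choice_table",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and ground-truth parameter ranges of a synthetic experiment.

    ``md_pairs`` fixes each item's (M, d) explicitly; otherwise pairs are drawn
    uniformly from ``m_range`` x ``d_range``, rejecting infeasible draws
    (M + d > 1).  ``world_layout`` lists (participants, init_a, init_b) per
    world; every item uses the same layout.
    """

    name: str
    n_items: int
    world_layout: tuple            # ((horizon, init_a, init_b), ...)
    control_n: int = 200
    m_range: tuple = (0.0, 0.5)
    d_range: tuple = (0.0, 0.4)
    md_pairs: tuple | None = None
    party: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_items < 1 or self.control_n < 1 or not self.world_layout:
            raise ValueError("all design counts must be >= 1")
        if self.md_pairs is not None:
            if len(self.md_pairs) != self.n_items:
                raise ValueError("md_pairs must list one (M, d) pair per item")
            for m, d in self.md_pairs:
                if not check_feasibility(m, d):
                    raise ValueError(f"infeasible (M, d) = ({m}, {d})")


@dataclass(frozen=True)
class Fixture:
    """Generated experiment: the choice table plus per-item ground truth."""

    table: ChoiceTable
    truth: tuple      # dicts: item_id, M, d, low, high (curve levels)
    design: ExperimentDesign


def v2019_like(seed: int = 0, md_pairs=None) -> ExperimentDesign:
    """Seven taste items, two worlds: one unseeded world of 530 participants
    and one of 3500 with a planted ~110:10 advantage for option A."""
    return ExperimentDesign(name="v2019_like", n_items=7,
                            world_layout=((530, 1, 1), (3500, 110, 10)),
                            m_range=(0.0, 0.2), d_range=(0.1, 0.5),
                            md_pairs=md_pairs, seed=seed)


def mdrt2019_like(seed: int = 0, md_pairs=None) -> ExperimentDesign:
    """Twenty statements, eight worlds of 230 participants, sign-only party
    signal; large marginal majority effects, small ideological content."""
    return ExperimentDesign(name="mdrt2019_like", n_items=20,
                            world_layout=tuple((230, 0, 0) for _ in range(8)),
                            control_n=460, m_range=(0.065, 0.35),
                            d_range=(0.0, 0.15), md_pairs=md_pairs,
                            party=True, seed=seed)


def fv2021_like(seed: int = 0, md_pairs=None) -> ExperimentDesign:
    """Thirty trivia questions, 12 worlds of 100 participants; both M and d
    vary widely across items."""
    return ExperimentDesign(name="fv2021_like", n_items=30,
                            world_layout=tuple((100, 1, 1) for _ in range(12)),
                            m_range=(0.0, 0.5), d_range=(0.0, 0.5),
                            md_pairs=md_pairs, seed=seed)


def _draw_md(rng, design: ExperimentDesign, i: int) -> tuple[float, float]:
    if design.md_pairs is not None:
        return tuple(map(float, design.md_pairs[i]))
    while True:
        m = rng.uniform(*design.m_range)
        d = rng.uniform(*design.d_range)
        if check_feasibility(m, d):
            return m, d


def generate_experiment(design: ExperimentDesign) -> Fixture:
    """Generate a full synthetic experiment, deterministic in ``design.seed``."""
    master = np.random.SeedSequence(design.seed)
    logger.info("generating %s from master seed %s", design.name, design.seed)
    item_seeds = master.spawn(design.n_items)
    rows = []
    world_init = {}
    truth = []
    for i, item_ss in enumerate(item_seeds):
        item = f"item{i:02d}"
        rng = np.random.default_rng(item_ss)
        m, d = _draw_md(rng, design, i)
        if design.party:
            truth.append({"item_id": item, "M": m, "d": d})
            _party_item_rows(rows, item, m, d, design, rng)
        else:
            curve = StepCurve.from_md(m, d)
            truth.append({"item_id": item, "M": m, "d": d,
                          "low": curve.low, "high": curve.high})
            # social worlds
            for w, (horizon, ia, ib) in enumerate(design.world_layout):
                world = f"w{w}"
                world_init[(item, world)] = (ia, ib)
                _, _, choices, _ = _simulate_paths(curve, ia, ib, horizon, 1,
                                                   rng, record=True)
                for t, chose in enumerate(choices[:, 0], start=1):
                    rows.append((item, world, t, "A" if chose else "B", "social", ""))
            # control condition: Bernoulli with p_A = g(1/2) = (1 - d)/2
            p_ctrl = (1.0 - d) / 2.0
            ctrl = rng.random(design.control_n) < p_ctrl
            for t, chose in enumerate(ctrl, start=1):
                rows.append((item, "control", t, "A" if chose else "B", "control", ""))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["party"])
    table = ChoiceTable(df=df, world_init=world_init)
    return Fixture(table=table, truth=tuple(truth), design=design)


def _party_item_rows(rows, item, m, d, design, rng):
    """Social worlds + control rows for one sign-only party item."""
    for w, (horizon, _, _) in enumerate(design.world_layout):
        world = f"w{w}"
        spec = party_spec_from_md(m, d, horizon=horizon, assignment="random",
                                  seed=rng.integers(2 ** 31))
        traj = simulate_party_trial(spec)
        for t in range(horizon):
            rows.append((item, world, t + 1,
                         "support" if traj.support[t] else "oppose",
                         "social", traj.party[t]))
    # control: party-P members support with p_ind_P, no social signal
    p_ind = {"A": (1.0 - d) / 2.0, "B": (1.0 + d) / 2.0}
    parties = np.where(rng.random(design.control_n) < 0.5, "A", "B")
    for t, pty in enumerate(parties, start=1):
        s = rng.random() < p_ind[pty]
        rows.append((item, "control", t, "support" if s else "oppose",
                     "control", pty))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CHOICE_CODES = {"A", "B", "support", "oppose"}


def write_choice_table(table: ChoiceTable, csv_path, sidecar_path=None) -> None:
    """Write the table as CSV plus a JSON sidecar with per-world init counts."""
    csv_path = Path(csv_path)
    table.df.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".init.json")
    sidecar = {}
    for (item, world), (ia, ib) in table.world_init.items():
        sidecar.setdefault(item, {})[world] = [int(ia), int(ib)]
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_choice_table(csv_path, sidecar_path=None) -> ChoiceTable:
    """Read a choice table, validating the schema.

    Raises ValueError naming the offending column, row or (item, world) on
    missing headers, unknown choice codes or non-contiguous participant
    indices.  A missing sidecar defaults every world to (0, 0) initial counts
    with a logged warning.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype={"item_id": str, "world_id": str},
                     keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing required headers {missing}")
    bad = ~df["choice"].astype(str).isin(_CHOICE_CODES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{csv_path}: unknown choice code "
                         f"{df.loc[bad.idxmax(), 'choice']!r} at line {line}")
    df["t"] = df["t"].astype(int)
    if "party" not in df.columns:
        df["party"] = ""
    world_init = {}
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".init.json")
    sidecar_path = Path(sidecar_path)
    if sidecar_path.exists():
        raw = json.loads(sidecar_path.read_text())
        for item, worlds in raw.items():
            for world, (ia, ib) in worlds.items():
                world_init[(item, world)] = (int(ia), int(ib))
    else:
        logger.warning("no init-count sidecar at %s; defaulting all worlds to (0, 0)",
                       sidecar_path)
    table = ChoiceTable(df=df, world_init=world_init)
    table.validate()
    return table
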