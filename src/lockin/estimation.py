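"""Estimation pipeline for multiple-world sequential choice experiments.

From a long-format table of choices (one row per participant, with item,
world, 1-based position t, chosen option and condition) the pipeline

1. attaches to each social-condition record the running popularity of option A
   in the participant's world, seeded by per-world artificial initial counts;
2. bins records by popularity (default bin width 0.1, half weights on bin
   edges, records at exactly 1/2 excluded) and estimates the influence curve
   per bin;
3. estimates the marginal majority effect M as the rise between the two
   central bins, (0.4, 0.5) to (0.5, 0.6);
4. identifies option A as the less popular option in the control condition and
   estimates the inherent appeal difference d = p_B - p_A there;
5. flags end-of-trial lock-in (option A holding a strict majority of choices
   in at least one world) and cross-tabulates (M > d) against lock-in.

A sign-only party variant mirrors the same steps for experiments where
participants observe only which of two groups shows larger support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError
from .equilibria import enters_lock_in_region

__all__ = [
    "ChoiceTable",
    "BinnedCurve",
    "PartyCurve",
    "ItemEstimate",
    "ClassificationTable",
    "attach_running_popularity",
    "bin_influence_curve",
    "estimate_M",
    "estimate_d_and_option_A",
    "party_estimates",
    "estimate_item",
    "estimate_experiment",
    "classify_items",
]

REQUIRED_COLUMNS = ("item_id", "world_id", "t", "choice", "condition")
_EDGE_TOL = 1e-12


@dataclass
class ChoiceTable:
    """Long-format experiment records plus per-world artificial initial counts.

    ``df`` columns: item_id, world_id, t (1-based within each item/world),
    choice, condition ('social' or 'control'), optionally party ('A'/'B').
    ``world_init`` maps (item_id, world_id) to (init_a, init_b); worlds absent
    from the map default to (0, 0).
    """

    df: pd.DataFrame
    world_init: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        bad = set(self.df["condition"]) - {"social", "control"}
        if bad:
            raise ValueError(f"unknown condition codes: {sorted(bad)}")
        for (item, world), grp in self.df.groupby(["item_id", "world_id"], sort=False):
            ts = np.sort(grp["t"].to_numpy())
            if not np.array_equal(ts, np.arange(1, len(ts) + 1)):
                raise ValueError(
                    f"participant index t not contiguous from 1 in item "
                    f"{item!r}, world {world!r}")

    def init_counts(self, item, world) -> tuple[int, int]:
        return tuple(self.world_init.get((item, world), (0, 0)))


def attach_running_popularity(table: ChoiceTable, option_a: str = "A",
                              item: str | None = None) -> pd.DataFrame:
    """Return the social-condition records with columns ``x`` and ``x_defined``.

    x_t = (init_a + #A among the first t-1 choices) / (init_a + init_b + t - 1).
    Records whose denominator is zero (no priors and no initial counts) get
    ``x_defined = False`` and NaN popularity; they are flagged, not dropped,
    and excluded from curve estimation downstream.
    """
    df = table.df
    if item is not None:
        df = df[df["item_id"] == item]
    soc = df[df["condition"] == "social"].reset_index(drop=True)
    xs = np.full(len(soc), np.nan)
    pos = 0
    for (it, world), grp in soc.groupby(["item_id", "world_id"], sort=False):
        grp = grp.sort_values("t")
        ia, ib = table.init_counts(it, world)
        chose_a = (grp["choice"] == option_a).to_numpy()
        prior_a = np.concatenate([[0], np.cumsum(chose_a)[:-1]])
        t = grp["t"].to_numpy()
        denom = ia + ib + t - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(denom > 0, (ia + prior_a) / np.maximum(denom, 1), np.nan)
        xs[soc.index.get_indexer(grp.index)] = x
        pos += len(grp)
    soc["x"] = xs
    soc["x_defined"] = ~np.isnan(xs)
    soc["chose_a"] = soc["choice"] == option_a
    return soc


@dataclass(frozen=True)
class BinnedCurve:
    """Binned empirical influence curve: per-bin effective counts (half weights
    allowed), choice-share estimates and binomial standard errors."""

    edges: np.ndarray
    counts: np.ndarray      # effective weights per bin
    estimates: np.ndarray   # NaN where the bin is empty
    ses: np.ndarray
    n_excluded_half: float  # records at exactly x = 1/2 that were excluded

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def bin_influence_curve(x: Sequence[float], chose_a: Sequence[bool],
                        bin_width: float = 0.1,
                        exclude_half: bool = True) -> BinnedCurve:
    """Estimate the influence curve on bins of width ``bin_width`` over [0, 1].

    Records falling exactly on an interior bin edge contribute weight 1/2 to
    each adjacent bin; records at exactly x = 1/2 are excluded when
    ``exclude_half`` (the marginal majority effect is defined away from 1/2).
    NaN popularities are ignored.
    """
    x = np.asarray(x, dtype=float)
    chose_a = np.asarray(chose_a, dtype=float)
    keep = ~np.isnan(x)
    x, chose_a = x[keep], chose_a[keep]
    if x.size == 0:
        raise EstimationError("no records with defined popularity to bin")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    w = np.zeros(n_bins)
    wa = np.zeros(n_bins)
    n_excluded = 0.0
    for xi, ci in zip(x, chose_a):
        if exclude_half and abs(xi - 0.5) < _EDGE_TOL:
            n_excluded += 1.0
            continue
        # interior edge -> half weight in each adjacent bin
        k = xi / bin_width
        nearest = round(k)
        if 0 < nearest < n_bins and abs(k - nearest) * bin_width < _EDGE_TOL:
            for b in (nearest - 1, nearest):
                w[b] += 0.5
                wa[b] += 0.5 * ci
        else:
            b = min(int(math.floor(k)), n_bins - 1)
            w[b] += 1.0
            wa[b] += ci
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(w > 0, wa / np.maximum(w, 1e-300), np.nan)
        ses = np.where(w > 0, np.sqrt(np.clip(est * (1 - est), 0, None)
                                      / np.maximum(w, 1e-300)), np.nan)
    return BinnedCurve(edges=edges, counts=w, estimates=est, ses=ses,
                       n_excluded_half=n_excluded)


def estimate_M(binned: BinnedCurve) -> tuple[float, float]:
    """Marginal majority effect: rise of the binned curve between the two
    central bins, with a quadrature standard error.

    Raises :class:`EstimationError` when either central bin is empty (the
    "no data to estimate M" case).
    """
    mids = binned.midpoints
    # the two bins adjacent to 1/2
    i_right = int(np.searchsorted(binned.edges, 0.5 + _EDGE_TOL)) - 1
    i_left = i_right - 1
    if i_left < 0 or i_right >= len(mids):
        raise EstimationError("binning does not straddle popularity 1/2")
    if binned.counts[i_left] <= 0 or binned.counts[i_right] <= 0:
        raise EstimationError("empty central bin: no data to estimate M")
    m = float(binned.estimates[i_right] - binned.estimates[i_left])
    se = float(np.hypot(binned.ses[i_left], binned.ses[i_right]))
    return m, se


def estimate_d_and_option_A(control_choices: Sequence) -> tuple[str, float, float]:
    """Identify option A and estimate the inherent appeal difference from the
    control condition (no social influence).

    A is the option chosen by fewer control participants (lexicographically
    smaller label on an exact tie); d-hat = p_B - p_A >= 0 with standard error
    2 * sqrt(p_A (1 - p_A) / n).
    """
    choices = pd.Series(list(control_choices))
    if choices.empty:
        raise EstimationError("no control records to identify option A")
    counts = choices.value_counts()
    labels = sorted(counts.index)
    if len(labels) > 2:
        raise ValueError(f"more than two options in control data: {labels}")
    if len(labels) == 1:
        # unanimous control: the never-chosen rival is option A
        complement = {"A": "B", "B": "A", "support": "oppose", "oppose": "support"}
        if labels[0] not in complement:
            raise EstimationError(
                f"control is unanimous for {labels[0]!r}; rival label unknown")
        labels = [complement[labels[0]], labels[0]]
    n = len(choices)
    a, b = sorted(labels, key=lambda l: (counts.get(l, 0), l))
    if counts.get(a, 0) == counts.get(b, 0):
        a, b = sorted((a, b))  # documented lexicographic tie-break
    p_a = counts.get(a, 0) / n
    d_hat = 1.0 - 2.0 * p_a
    se = 2.0 * math.sqrt(p_a * (1 - p_a) / n)
    return a, float(d_hat), float(se)


# ---------------------------------------------------------------------------
# Party (sign-only signal) variant
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartyCurve:
    """Two-point empirical curve for the sign-only party process: the value
    y = y_A - y_B of the support-difference curve on each side of x = 0."""

    y_minus: float
    y_plus: float
    n_minus: float
    n_plus: float
    n_ignored: int  # records with x = 0 or undefined, ignored by convention


def _party_running_x(df: pd.DataFrame, party_a: str) -> np.ndarray:
    """Per-record x = x_A - x_B over prior same-world, same-party supporters.

    NaN until both parties have at least one prior participant in the world.
    """
    xs = np.full(len(df), np.nan)
    for _, grp in df.groupby("world_id", sort=False):
        grp = grp.sort_values("t")
        cnt = {True: 0, False: 0}
        sup = {True: 0, False: 0}
        for row_pos, (_, row) in enumerate(grp.iterrows()):
            if cnt[True] > 0 and cnt[False] > 0:
                xs[df.index.get_loc(row.name)] = (sup[True] / cnt[True]
                                                  - sup[False] / cnt[False])
            is_a = row["party"] == party_a
            cnt[is_a] += 1
            sup[is_a] += int(row["support"])
    return xs


def party_estimates(social: pd.DataFrame, control: pd.DataFrame
                    ) -> tuple[PartyCurve, tuple[float, float], tuple[float, float], str]:
    """Estimate M and d for a sign-only party experiment.

    ``social`` and ``control`` need columns world_id, t, party, support (0/1).
    Party A is the party less likely to support the statement in the control
    condition.  Records with x = 0 (or undefined x) are ignored; the rest are
    grouped by the sign of x.  Within each group, y_P is the support share of
    party-P members; M_P is y_P(x > 0) - y_P(x < 0), and

        M = (M_A - M_B) / 2,     d = p_ind_B - p_ind_A  (control support shares).

    Returns (PartyCurve, (M, se_M), (d, se_d), party_a).
    """
    for frame, name in ((social, "social"), (control, "control")):
        for col in ("party", "support"):
            if col not in frame.columns:
                raise ValueError(f"{name} records need a {col!r} column")
    ctrl_shares = control.groupby("party")["support"].agg(["mean", "size"])
    if len(ctrl_shares) < 2:
        raise EstimationError("control data must cover both parties")
    party_a = ctrl_shares["mean"].idxmin()
    if ctrl_shares["mean"].nunique() == 1:
        party_a = sorted(ctrl_shares.index)[0]
    party_b = [p for p in ctrl_shares.index if p != party_a][0]

    social = social.copy()
    social["x"] = _party_running_x(social, party_a)
    usable = social[social["x"].notna() & (social["x"] != 0.0)]
    groups = {}
    for sign, grp in ((+1, usable[usable["x"] > 0]), (-1, usable[usable["x"] < 0])):
        if grp.empty:
            raise EstimationError(f"no records with sign({'x'}) = {sign:+d}; "
                                  "party curve undefined on that side")
        stats = {}
        for pty in (party_a, party_b):
            sub = grp[grp["party"] == pty]["support"]
            if sub.empty:
                raise EstimationError(
                    f"party {pty!r} has no records on the x {sign:+d} side")
            p = sub.mean()
            stats[pty] = (p, math.sqrt(p * (1 - p) / len(sub)), len(sub))
        groups[sign] = stats

    def y_diff(sign):
        return groups[sign][party_a][0] - groups[sign][party_b][0]

    m_a = groups[+1][party_a][0] - groups[-1][party_a][0]
    m_b = groups[+1][party_b][0] - groups[-1][party_b][0]
    m_hat = (m_a - m_b) / 2.0
    se_m = 0.5 * math.sqrt(sum(groups[s][p][1] ** 2
                               for s in (+1, -1) for p in (party_a, party_b)))
    p_ind = {p: ctrl_shares.loc[p, "mean"] for p in (party_a, party_b)}
    d_hat = p_ind[party_b] - p_ind[party_a]
    se_d = math.sqrt(sum(p_ind[p] * (1 - p_ind[p]) / ctrl_shares.loc[p, "size"]
                         for p in (party_a, party_b)))
    curve = PartyCurve(y_minus=y_diff(-1), y_plus=y_diff(+1),
                       n_minus=sum(groups[-1][p][2] for p in (party_a, party_b)),
                       n_plus=sum(groups[+1][p][2] for p in (party_a, party_b)),
                       n_ignored=int(len(social) - len(usable)))
    return curve, (float(m_hat), float(se_m)), (float(d_hat), float(se_d)), party_a


# ---------------------------------------------------------------------------
# Per-item pipeline and classification
# ---------------------------------------------------------------------------

@dataclass
class ItemEstimate:
    """Per-item summary: estimated M and d, lock-in flag, and diagnostics.

    ``m_hat`` is reported raw (negative values possible from noise) and is
    None when the central bins carry no data.
    """

    item_id: str
    option_a: str
    m_hat: float | None
    m_se: float | None
    d_hat: float
    d_se: float
    lock_in_observed: bool
    n_trials: int
    enters_lock_in: bool | None
    n_central: float = 0.0

    @property
    def mm_condition(self) -> bool | None:
        if self.m_hat is None:
            return None
        return self.m_hat > self.d_hat


def estimate_item(table: ChoiceTable, item: str, bin_width: float = 0.1,
                  exclude_half: bool = True) -> ItemEstimate:
    """Run the full standard (non-party) pipeline for a single item."""
    df = table.df[table.df["item_id"] == item]
    if df.empty:
        raise EstimationError(f"no records for item {item!r}")
    control = df[df["condition"] == "control"]["choice"]
    option_a, d_hat, d_se = estimate_d_and_option_A(control)
    soc = attach_running_popularity(table, option_a=option_a, item=item)

    binned = bin_influence_curve(soc.loc[soc["x_defined"], "x"],
                                 soc.loc[soc["x_defined"], "chose_a"],
                                 bin_width=bin_width, exclude_half=exclude_half)
    try:
        m_hat, m_se = estimate_M(binned)
        n_central = float(binned.counts[np.searchsorted(binned.edges, 0.5 + _EDGE_TOL) - 2:
                                        np.searchsorted(binned.edges, 0.5 + _EDGE_TOL)].sum())
    except EstimationError:
        m_hat = m_se = None
        n_central = 0.0
    try:
        enters = enters_lock_in_region(binned)
    except Exception:
        enters = None

    # lock-in: option A holds a strict end-of-trial majority in >= 1 world
    ends = soc.groupby("world_id")["chose_a"].mean()
    lock_in = bool((ends > 0.5).any())
    return ItemEstimate(item_id=item, option_a=option_a, m_hat=m_hat, m_se=m_se,
                        d_hat=d_hat, d_se=d_se, lock_in_observed=lock_in,
                        n_trials=int(ends.size), enters_lock_in=enters,
                        n_central=n_central)


def _estimate_party_item(table: ChoiceTable, item: str) -> ItemEstimate:
    df = table.df[table.df["item_id"] == item].copy()
    df["support"] = (df["choice"].astype(str).isin(["support", "1", "True"])).astype(int)
    soc = df[df["condition"] == "social"]
    ctrl = df[df["condition"] == "control"]
    curve, (m_hat, m_se), (d_hat, d_se), party_a = party_estimates(soc, ctrl)
    ends = []
    for _, grp in soc.groupby("world_id", sort=False):
        a = grp["party"] == party_a
        if a.any() and (~a).any():
            ends.append(grp.loc[a, "support"].mean() - grp.loc[~a, "support"].mean())
    ends = np.asarray(ends)
    return ItemEstimate(item_id=item, option_a=party_a, m_hat=m_hat, m_se=m_se,
                        d_hat=d_hat, d_se=d_se,
                        lock_in_observed=bool((ends > 0.0).any()),
                        n_trials=int(ends.size),
                        enters_lock_in=bool(curve.y_plus > 0),
                        n_central=float(curve.n_plus + curve.n_minus))


def estimate_experiment(table: ChoiceTable, bin_width: float = 0.1,
                        party: bool = False) -> list[ItemEstimate]:
    """Per-item estimates for every item in the table."""
    table.validate()
    items = table.df["item_id"].unique()
    if party:
        return [_estimate_party_item(table, it) for it in items]
    return [estimate_item(table, it, bin_width=bin_width) for it in items]


@dataclass(frozen=True)
class ClassificationTable:
    """2x2 cross-tabulation of the lock-in criterion against observed lock-in."""

    counts: dict                 # keys (mm_condition, lock_in_observed)
    no_estimate: tuple           # item ids lacking an M estimate
    per_item: pd.DataFrame

    @property
    def n_items(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def accuracy(self) -> float:
        agree = self.counts[(True, True)] + self.counts[(False, False)]
        return agree / self.n_items if self.n_items else float("nan")


def classify_items(estimates: Iterable[ItemEstimate]) -> ClassificationTable:
    """Cross-tabulate (M-hat > d-hat) against observed lock-in across items.

    Items without an M estimate (empty central bin) are excluded from the 2x2
    table and listed separately.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one item estimate")
    counts = {(a, b): 0 for a in (True, False) for b in (True, False)}
    skipped = []
    rows = []
    for e in estimates:
        rows.append({"item_id": e.item_id, "m_hat": e.m_hat, "d_hat": e.d_hat,
                     "mm_condition": e.mm_condition,
                     "lock_in_observed": e.lock_in_observed,
                     "n_trials": e.n_trials})
        if e.mm_condition is None:
            skipped.append(e.item_id)
        else:
            counts[(e.mm_condition, e.lock_in_observed)] += 1
    return ClassificationTable(counts=counts, no_estimate=tuple(skipped),
                               per_item=pd.DataFrame(rows))
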