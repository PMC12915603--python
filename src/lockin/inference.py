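"""Aggregate statistics: regression of lock-in on item parameters and
Poisson-binomial bounds on the total number of lock-in occurrences.

Two regressions compare explanations of lock-in proneness across items: a
one-parameter logistic model in M - d with no intercept (the theory pins the
threshold at M - d = 0) against a two-parameter model in d with intercept,
plus nonparametric Nadaraya-Watson fits of both.  The aggregate test draws the
total lock-in count under the per-item probability lower bounds (a Poisson
binomial with each item's bound repeated once per trial) and reports the
one-sided 95% lower confidence bound as the 5% quantile of the simulated
totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelFit",
    "KernelFit",
    "AggregateTest",
    "fit_lockin_logistic",
    "fit_lockin_kernel",
    "aggregate_lock_in_test",
]

_CLIP = 1e-6


def _binary_ll(y: np.ndarray, p: np.ndarray, clip: float = _CLIP) -> float:
    p = np.clip(p, clip, 1.0 - clip)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood logistic fit with the standard comparison metrics."""

    coefficients: np.ndarray
    llf: float
    aic: float
    bic: float
    mcfadden_r2: float
    fitted: np.ndarray
    separation_flag: bool
    degenerate_outcomes: bool
    n_params: int
    n_obs: int


@dataclass(frozen=True)
class KernelFit:
    """Nadaraya-Watson (Gaussian kernel, local constant) fit of binary outcomes."""

    bandwidth: float
    fitted: np.ndarray
    llf: float
    r_squared: float  # squared correlation of fitted values with outcomes


@dataclass(frozen=True)
class AggregateTest:
    """Simulated lower bound on the total lock-in count plus per-item p-values."""

    per_trial_probs: np.ndarray
    lower_bound_95: int
    expected_total: float
    observed_total: int
    per_item_pvalues: np.ndarray
    reject: bool
    reps: int


def _null_llf(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only model (fitted probability = mean)."""
    return _binary_ll(y, np.full_like(y, y.mean(), dtype=float))


def fit_lockin_logistic(outcomes, regressor, with_intercept: bool) -> ModelFit:
    """Logistic regression of a binary outcome on a single regressor.

    ``with_intercept=False`` fits the one-parameter threshold model (used with
    M - d, where the theory fixes the threshold at 0).  McFadden's R^2 uses the
    intercept-only null in both cases.  Perfect separation is detected and
    flagged; coefficients then sit at the optimizer's stopping point and the
    fit should be read as a divergent maximum-likelihood boundary case.
    """
    y = np.asarray(outcomes, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValueError("need equal-length outcome/regressor arrays with n >= 2")
    degenerate = bool(np.all(y == y[0]))
    exog = sm.add_constant(x) if with_intercept else x[:, None]
    k = exog.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, exog)
        try:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
        except Exception:
            res = model.fit(disp=0, method="nm", maxiter=2000)
    fitted = np.asarray(res.predict(exog))
    # complete separation: the likelihood supremum (0) is approached as the
    # coefficient diverges.  With an intercept this happens iff some cut point
    # in x splits the outcomes perfectly; without one the cut is fixed at 0.
    if degenerate:
        separation = False
    elif with_intercept:
        separation = bool(x[y == 0].max() < x[y == 1].min() or
                          x[y == 1].max() < x[y == 0].min())
    else:
        separation = bool((np.all(x[y == 1] > 0) and np.all(x[y == 0] < 0)) or
                          (np.all(x[y == 1] < 0) and np.all(x[y == 0] > 0)))
    llf = float(res.llf)
    ll0 = _null_llf(y) if not degenerate else float("nan")
    mcf = float("nan") if degenerate else 1.0 - llf / ll0
    return ModelFit(coefficients=np.asarray(res.params), llf=llf,
                    aic=2 * k - 2 * llf, bic=k * np.log(y.size) - 2 * llf,
                    mcfadden_r2=mcf, fitted=fitted, separation_flag=separation,
                    degenerate_outcomes=degenerate, n_params=k, n_obs=y.size)


def _nw_fit(x: np.ndarray, y: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel locally constant (Nadaraya-Watson) fitted values."""
    if not np.isfinite(bandwidth):
        return np.full_like(y, y.mean(), dtype=float)
    z = (x[:, None] - x[None, :]) / bandwidth
    w = np.exp(-0.5 * z ** 2)
    return (w @ y) / w.sum(axis=1)


def fit_lockin_kernel(outcomes, regressor, bandwidth: float | None = None) -> KernelFit:
    """Nadaraya-Watson regression of a binary outcome on a single regressor.

    The bandwidth is chosen by least-squares leave-one-out cross-validation
    (statsmodels ``KernelReg(bw='cv_ls')``) unless given explicitly; an
    infinite bandwidth (or a constant regressor) degrades to the global mean.
    The log-likelihood clips fitted probabilities to [1e-6, 1 - 1e-6].
    """
    y = np.asarray(outcomes, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if np.unique(x).size < 2:
        fitted = np.full_like(y, y.mean())
        return KernelFit(bandwidth=float("nan"), fitted=fitted,
                         llf=_binary_ll(y, fitted), r_squared=0.0)
    if bandwidth is None:
        from statsmodels.nonparametric.kernel_regression import KernelReg
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kr = KernelReg(endog=y, exog=x, var_type="c", reg_type="lc", bw="cv_ls")
        bandwidth = float(kr.bw[0])
    fitted = _nw_fit(x, y, bandwidth)
    if np.std(fitted) < 1e-12 or np.std(y) < 1e-12:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return KernelFit(bandwidth=float(bandwidth), fitted=fitted,
                     llf=_binary_ll(y, fitted), r_squared=r2)


def aggregate_lock_in_test(item_bounds, trials_per_item, observed_total: int,
                           observed_per_item=None, reps: int = 100_000,
                           seed=None) -> AggregateTest:
    """Test the observed total lock-in count against the per-item bounds.

    Each of an item's trials is an independent success with that item's
    probability lower bound, so the total is Poisson-binomial; ``reps``
    simulated totals give the one-sided 95% lower confidence bound as the 5%
    quantile (the 5000th smallest draw at reps = 1e5).  Per-item p-values are
    binomial probabilities of observing at most the item's count (at most 0
    when per-item counts are not supplied).
    """
    p = np.asarray(item_bounds, dtype=float)
    n = np.asarray(trials_per_item, dtype=int)
    if p.shape != n.shape:
        raise ValueError("item_bounds and trials_per_item must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("bounds must be probabilities")
    if reps < 10_000:
        raise ValueError("need reps >= 10000 for a stable 5% quantile")
    rng = np.random.default_rng(seed)
    totals = np.zeros(reps, dtype=np.int64)
    for pi, ni in zip(p, n):
        totals += rng.binomial(ni, pi, size=reps)
    totals.sort()
    lower = int(totals[int(np.ceil(0.05 * reps)) - 1])
    if observed_per_item is None:
        k = np.zeros_like(n)
    else:
        k = np.asarray(observed_per_item, dtype=int)
    pvals = stats.binom.cdf(k, n, p)
    per_trial = np.repeat(p, n)
    return AggregateTest(per_trial_probs=per_trial, lower_bound_95=lower,
                         expected_total=float(per_trial.sum()),
                         observed_total=int(observed_total),
                         per_item_pvalues=np.asarray(pvals),
                         reject=observed_total < lower, reps=reps)
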