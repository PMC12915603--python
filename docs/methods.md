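# Methods

This note documents the model, the estimators, the numerical choices and the
design decisions behind the package, and what the synthetic experiments do and
do not establish about real data.

## Model and assumptions

The process is a generalized Pólya urn: participant `t` observes the current
popularity of option A,

    x_t = (init_a + #A among the first t−1 choices) / (init_a + init_b + t − 1),

and chooses A with probability `f(x_t)` for a nondecreasing influence curve
`f: [0,1] → [0,1]`.  Standing assumptions (inherited from the underlying
theory): `f` crosses the diagonal wherever it meets it, does so finitely many
times, and its only admissible discontinuity is at `x = 1/2`.  Under these
assumptions the popularity converges almost surely to an equilibrium;
down-crossings of the diagonal are the possible limits (stable equilibria) and
up-crossings separate their basins (the critical mass).

Conventions chosen here and used consistently:

* **Value at exactly 1/2.**  `u(1/2) = 0`, so `f(1/2) = g(1/2)`; a
  `StepCurve`'s default mid value is `(low + high)/2`.  Empirical records at
  exactly `x = 1/2` are excluded from curve estimation, so nothing observable
  depends on this convention.
* **Option A** is the inherently less appealing option (`d ≥ 0`).  In
  estimation it is identified from the control condition, with a documented
  lexicographic tie-break at an exact 50/50 split.
* **Finite horizons.**  `x_∞` is approximated by the end-of-trial value.  The
  dynamics module reports both the urn popularity (initial counts included)
  and the share of actual choices; the estimation pipeline's lock-in flag uses
  the choice share, matching how end-of-trial majorities are read off
  experiment data.  Lock-in is a *strict* majority (`x̄ > 0.5`, party variant
  `ȳ > 0`) in at least one world.

## Theory layer

`lock_in_probability_bound(M, d)` implements the closed form

    p_L ≥ 2(M−d)(1−d) / [(1−d)(1−d+M) + 2M],   M > d,

and `walk_survival_probability` the equivalent walk form
`q₀(2q₊−1)/(q₊ − q₀(1−q₊))` with `q₀ = (1−d)/2`, `q₊ = (1−d+M)/2`; the two are
verified to agree to 1e−12 across the feasible region.  `M ≤ d` raises an
error rather than returning 0: the theory asserts nothing there, and silent
zeros invite misreading the bound as an estimate.  The Monte-Carlo oracle
`mc_walk_survival` truncates "for all n" at a configurable horizon; with
`q₊ > 1/2` surviving walks drift away from the origin linearly, so the
truncation bias is exponentially small at the default horizon 10,000
(empirically invisible at Monte-Carlo resolution).

## Equilibrium analysis

`find_equilibria` scans `f(x) − x` on a 2001-point grid (configurable) and
refines each sign change by bisection to 1e−9.  Bisection also converges at
jump crossings, where it lands on the discontinuity at 1/2.  Stability is read
off the sign pattern on the two sides; sign patterns that do not cross, but
whose gap to the diagonal is below a 1e−6 margin, are labelled
`indeterminate` rather than silently classified.  Crossings at exactly 1/2
are reported but never counted as lock-in (the region is strict).

`enters_lock_in_region` is analytic for step curves (`high > 1/2`), and for
generic curves combines a grid scan on `(1/2, 1)` with a bounded local
refinement and the right limit at 1/2.  Binned empirical curves are assessed
at bin midpoints (estimate above a midpoint that is itself above 1/2).  The
midpoint rule is a deliberate, conservative choice: connecting bin estimates
with line segments would declare entry whenever a segment pokes above the
diagonal between midpoints, which depends on an interpolation convention the
data do not pin down.

`logistic_lock_in_threshold(d)` finds the smallest slope `b` for which the
logistic curve `f(x) = 1/(1 + ((1+d)/(1−d))·e^{b(1−2x)})` enters the lock-in
region, by bisection on the sign of `max_{x>1/2}(f(x) − x)`.  At the threshold
the curve is tangent to the diagonal (`f(x) = x`, `2bx(1−x) = 1`).  For
`d = 0` the threshold is exactly 2; for `d = 0.2` it is ≈ 2.98, i.e. slope 3
at integer resolution.

## Simulator

Ensembles are advanced in lockstep: one vector of uniforms per participant
index across all trials, from a single generator seeded by the master seed.
This keeps the whole ensemble reproducible (same seed ⇒ identical result) at
vectorised cost; it was preferred over spawning one stream per trial, which
costs two orders of magnitude more at the ensemble sizes used in the test
suite.  `simulate_trial` uses its own stream and additionally records the full
choice and popularity paths.

Default initial counts are (1, 1): the first participant then sees popularity
1/2, and the flat step process with levels `0 / (1−d)/2 / (1−d+M)/2` coincides
*exactly* with the survival walk (popularity ≥ 1/2 iff walk state ≥ 0), which
is what makes the Monte-Carlo confirmation of the bound an exact check rather
than an approximation.

The party variant draws each participant's support from one of four
probabilities indexed by party and by the sign of `x = x_A − x_B` (difference
of running within-party support shares).  While `x` is undefined (either party
unseen) or exactly 0, the mean of the two signal-conditional probabilities is
used, mirroring `u(0) = 0`.  `party_spec_from_md(M, d, ...)` constructs the
symmetric parameterisation `p±_A = (1−d±M)/2`, `p±_B = (1+d∓M)/2`, for which
the nominal marginal majority effect is `M` and the ideological content is
`d`.  The probability bound holds for this variant only under balanced party
arrival (alternating assignment); with fair random assignment it is
approximate.

## Estimators

* **Binning.**  Width 0.1 by default (configurable); records exactly on an
  interior edge count half in each adjacent bin, and records at exactly 1/2
  are excluded.  Per-bin standard errors are binomial, `√(p̂(1−p̂)/n_eff)`, and
  differences combine by quadrature — standard choices, made explicitly since
  the estimator itself does not dictate them.
* **M̂** is the difference of the `(0.5, 0.6)` and `(0.4, 0.5)` bin estimates.
  It is reported raw — negative values are possible under noise and are
  flagged, not clipped, since clipping would bias any scatter of `M̂` against
  `d̂`.  An empty central bin raises an estimation error ("no data to
  estimate M"), and such items are tabulated separately by `classify_items`.
  Known limitation: when the true `M` is large, the popularity spends little
  time near 1/2 (the equilibria are far from the centre), so the central bins
  are thin and `M̂` is noisy exactly where the effect is strongest.  For
  continuous curves `M̂` targets the difference of bin-averaged curve values —
  a small positive slope artifact, computable analytically, which the test
  suite checks against a bin-average oracle.
* **d̂** is `p̂_B − p̂_A` in the control condition, a consistent estimator of
  `1 − 2g(1/2)`.
* **Party variant.**  Records with `x = 0` (or undefined `x`; we require at
  least one prior participant of each party, and flag the rest) are ignored;
  the remaining records are grouped by the sign of `x`;
  `M̂ = (M̂_A − M̂_B)/2` and `d̂ = p̂_ind,B − p̂_ind,A` from the per-party control
  shares, keeping both on the [0, 1] scale of the standard variant.

## Inference layer

Logistic regression is delegated to statsmodels `Logit`; the one-parameter
model in `M − d` omits the intercept because the theory pins the threshold at
`M − d = 0`, whereas the model in `d` gets an intercept (no ex-ante
threshold).  McFadden's R² uses the intercept-only null in both cases — also
for the no-intercept model, so the two models are compared against the same
null.  Complete separation is detected geometrically (a perfect cut point in
the regressor; through the origin for the no-intercept model) and flagged
rather than hidden behind large coefficients.  Nadaraya–Watson fits use a
Gaussian kernel with least-squares leave-one-out cross-validated bandwidth
(statsmodels `KernelReg(bw='cv_ls')`); fitted values are recomputed with the
package's own evaluator so that forced and infinite bandwidths degrade cleanly
to the global mean.  Kernel log-likelihoods clip fitted probabilities to
`[1e−6, 1 − 1e−6]`.

The aggregate lock-in test treats every trial of item `i` as an independent
success with that item's probability bound, simulates the Poisson-binomial
total (sums of binomial draws per item — exact for repeated probabilities),
and reports the one-sided 95% lower confidence bound as the 5% quantile of
the simulated totals (the 5,000th smallest draw at 100,000 replicates).
Per-item p-values are binomial tail probabilities of observing at most the
item's count.

## Synthetic experiments

The generator emulates the three multiple-world designs the pipeline targets:
7 items × 2 worlds (530 and 3,500 participants, the large world seeded with a
planted ~110:10 advantage for the inferior option); 20 statements × 8 worlds
of 230 participants with the sign-only party signal plus control worlds; and
30 questions with ~12 worlds of 100 participants.  Ground truth per item is a
flat step curve `StepCurve.from_md(M, d)` (levels `(1−d∓M)/2`), drawn from
feasible ranges or supplied explicitly; control records are Bernoulli with
`p_A = (1−d)/2`, so `d̂` targets `1 − 2g(1/2)` by construction.  The default
control size is 200 per item, giving `d̂` a standard error of about 0.035.
One world of the first design uses unit initial counts where the original
design had none, because the urn needs a defined first popularity; estimation
treats zero-denominator records as flagged-undefined either way.

What the generator does *not* emulate: participant heterogeneity beyond the
aggregate curve, abstention, dropout, time-varying influence, and
non-stationary arrival of parties.  Passing recovery tests therefore show
that the estimators invert the model they assume, at realistic sample sizes —
not that real experiments satisfy that model.

Problem sizes in the test suite were chosen to keep statistical power high at
desk scale: ensembles of 1,000–2,000 trials at horizons 2,000–5,000 for the
dynamics properties, 100,000 replicates at horizon 10,000 for the Monte-Carlo
confirmation of the 13% worked example, and 20 items × 50 worlds × 200
participants for estimator recovery (where 2-standard-error coverage of the
truth is required for ≥ 90% of items, with the recovery items spread over the
feasible `(M, d)` region on both sides of the diagonal).

## Known limitations

* Jumps are supported only at `x = 1/2`; salient popularity values elsewhere
  are out of scope.
* Two options only; plurality/ranking effects among more options are not
  modelled.
* The exact (rather than bounded) lock-in probability for step curves is
  available only through the Monte-Carlo oracle, not in closed form.
* Equilibrium detection is grid-based; curves engineered to cross the
  diagonal inside a grid cell without a sign change at its endpoints (width
  < 5e−4 by default) could be missed — tighten `grid_n` for pathological
  inputs.
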