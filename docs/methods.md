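# Methods

## Model

Tumor development is modelled as a chain of compartments fed by a
logistically growing field of oncogene-transformed mammary epithelial
cells.  With `F` in cells and `O`, `S`, `L` in lesions:

* FSL: `dF = rF(1-F/K)`, `dS = p1 F - p2 S`, `dL = p2 S`
* FOSL: `dF = rF(1-F/K)`, `dO = p0 F - p1 O`, `dS = p1 O - p2 S`,
  `dL = p2 S`

Assumptions worth making explicit:

* **No field depletion.** The transition terms do not drain `F`.  At
  fitted values the outflow `p0·F ≈ 1e-5·F` per week is about five
  orders of magnitude below the logistic terms, and `F` counts cells
  while the downstream compartments count lesions, so a unit-consistent
  depletion term is ill-defined.  Numerically the choice is irrelevant
  at the fitted rates.
* **Time origin.** `t = 0` corresponds to 3 weeks of age, the earliest
  cell-count measurement; ages map to model time by `t = age - 3`.
  Initial state is `(F0, 0, 0[, 0])` — no lesions at initiation.
* **Mass-action transitions, no spatial structure, no interaction
  between tumor genotypes**, and no long-term dynamics for `L` beyond
  the observation window.

### Solving

The field equation is autonomous with the closed form
`F(t) = K / (1 + (K/F0 - 1) e^{-rt})` (overflow-safe for large `rt`).
`solve()` therefore performs an exact reduction: `F(t)` is evaluated
analytically and drives the linear lesion subsystem, which is
integrated with LSODA at `rtol = 1e-8`, `atol = 1e-10`.  Two
consequences: the field output is structurally independent of the
transition rates (so sensitivity indices of `p0/p1/p2` on `F` are
exactly zero), and accuracy against the constant-field closed form
`S(t) = (p1 K / p2)(1 - e^{-p2 t})` is ~1e-9 relative.  Negative
excursions beyond 1e-6 lesions raise `SolverError`; smaller ones are
clipped to zero.

## Estimation

**Field fit.** `(r, K, F0)` minimise the squared error between
digestion cell counts at weeks 3, 4 and 6 and the logistic solution.
Week-10 counts are kept for reporting but excluded from the objective
(ductal growth is essentially complete by 6 weeks, and later counts
reflect saturation plus lesion formation).  Bounds are data-driven and
deliberately loose — `K` within `[min(week6)/2, 2·max(week6)]`, `F0`
within the similarly widened week-3 range — because the field need not
have saturated by week 6: clamping `K` to the raw week-6 range would
bias `r` upward whenever `F(3 wk since init) < K`.  A fit ending at a
bound is flagged in the result.  If the fitted `F0` equals `K` the
curve is flat and `r` is unidentifiable; it is then pinned to its lower
bound rather than reported at an arbitrary value.

**Transition fit.** With the field fixed, rates minimise the per-mouse
sum of squared differences between observed and expected S and L counts
at each mouse's age, S and L weighted equally, each genotype fitted
independently.  Residuals are per mouse, not per timepoint mean, so
ages with more mice carry proportionally more weight.  Rates live in
`[1e-9, 1e2]` per week; the optimiser (trust-region-reflective least
squares) works in log10-parameter space because the bounds span eleven
decades and linear-space steps condition badly.  Multi-start: five
log-uniform draws plus one moment-matching start that scales the
field-outflow rate so the predicted mean tumor count matches the
observed mean.  A survey with no tumors at all short-circuits to the
lower bound.

Under FOSL the occult-to-small rate `p1` is weakly identified from
cross-sectional S/L counts — when occult transit is fast the model
collapses to FSL with inflow `p0`, so any sufficiently large `p1` fits
equally well.  The fit warns when `p1` lands on a bound; the bootstrap
quantifies the non-identifiability (intervals spanning more than an
order of magnitude), and the throughput parameters `p0` and `p2` remain
stable.

**Hierarchical bootstrap.** Per replicate: field parameters are
jittered `Normal(mean, 0.05·mean)` (negative draws redrawn — the
parameters are physically non-negative); mice are resampled with
replacement, then tumors with replacement within each sampled mouse
(the same number the mouse carries — a standard nonparametric
resample), restratified by genotype and S/L state; each synthetic
mouse's age receives a `Normal(0, 0.05 wk)` perturbation applied only
in the ODE evaluation; rates are refit warm-started from the point
estimate (a single start — replicate surfaces are close to the point
fit, and multi-starting every replicate would multiply cost for no
observed change in the draws).  Point estimates are medians of the
replicate draws; intervals are percentile (not BCa), at 80/90/95%
coverage by default.  Failed refits are excluded and counted; more than
10% failures aborts.  Everything is deterministic given the seed.

## Sensitivity screening

Morris one-at-a-time elementary effects, implemented in-package:
parameters are mapped to the unit hypercube over their ranges (default
±50% around the spec values), base points sit on an 8-level grid, and
each randomized trajectory perturbs every parameter once by
`delta = p/(2(p-1))` in random order and direction.  The statistic
`mu(t)` is the mean absolute effect across trajectories, computed at
every time point; unit-cube normalization makes `mu` comparable across
parameters whose scales differ by orders of magnitude.  Parameter order
is canonicalized internally so results are invariant to how the range
dictionary was assembled.  Only `mu` is reported (no sigma plots).
The headline behaviour — the occult transition `p0` dominates the
sensitivity of palpable output for both genotypes, with `K` (d16) and
`K`/`F0` (p95) next — is asserted for the default ranges; rankings
under very different ranges are not guaranteed.

## Lifetime risk simulation

`simulate_lifetime` integrates the FSL chain from a chosen initiation
age to 104 weeks (2 years, the expected lifespan of a captive mouse)
with the field frozen at a prescribed size (`r = 0`, `F0 = K = size`),
so field growth plays no role; the result is `E[L]` at the horizon,
exactly linear in field size.  Grid cells are classified by the legend
thresholds `E[L] < 0.5` (low), `0.5–1` (gradient), `>= 1` (one or
more).  The expectation is the default risk measure because the top
class is phrased as "one or more tumors"; a Poisson transform
`P(>=1) = 1 - e^{-E[L]}` is available for readers who prefer a
probability, in which case the top class is unreachable except by
rounding and the gradient class carries the "high probability" meaning.

## Observable-phase analytics

* **TVDT**: `ln 2 / b` with `b` the least-squares slope of ln(volume)
  on age; series with fewer than 3 measurements, or slope at or below
  rounding level, are excluded (reported as `None`), never crashes.
* **Initiation age**: `t_first - TVDT · log2(V_first / V_ref)` assuming
  constant doubling.  The reference volume defaults to 1e-6 mm³
  (roughly one cell) but is consequential and must be logged by
  callers; back-extrapolated ages are therefore not treated as
  quantitative reproductions of any reported value.
* **Palpability cutoff**: the 15th percentile of palpable tumor areas,
  linear-interpolation definition (pinned by test).  Caliper volume
  uses `V = L·W²/2` and projected area `A = π·L·W/4`; both conversions
  are isolated in one place so the cutoff pipeline can be re-based.
* **Tumor-free survival**: Kaplan–Meier product-limit curve (lifelines
  under the hood); the median is the first observed time with survival
  at or below 0.5 (pinned by test).
* **Mutation burden**: group means of per-tumor totals, truncated to
  integer for comparison with reported values; every row is validated
  against `total = sum of type counts`.

## Synthetic cohorts

The generator reproduces the study design, not just its distributions:
digestion counts at weeks 3/4/6/10 (3 mice at week 3, 4 at the others)
as the logistic curve times mean-one log-normal noise at 10% CV;
120 survey mice assigned sacrifice ages cycling over a 10–20-week grid
in 0.5-week (3.5-day) steps, with per-mouse, per-genotype S and L
counts Poisson around the ODE expectations; palpation series surfacing
at 20 mm³ around a 113-day mean onset age, doubling every
`Normal(12, 0.2·12)` days (truncated positive), measured every 3.5 days
with 5% caliper noise until 2000 mm³; mutation totals negative-binomial
(`var = mean + 0.2·mean²`) around the published group means with
multinomial type splits.  Poisson per-mouse counts are the minimal
count model consistent with fitting means to per-mouse integer data;
true between-mouse dispersion is unknowable from survey means, so the
count model is isolated behind the config.  Survey areas are drawn
class-conditionally (S log-uniform on `[0.25, cutoff)`; L log-normal at
or above the cutoff), so classification is exact by construction — only
the supports matter to the fitting pipeline.

What passing recovery tests on these cohorts shows: the estimation
machinery is consistent under the model's own assumptions at the
published parameter values and study size.  What it does not show:
robustness to overdispersed counts, misclassified areas near the
cutoff, missed necropsies, or between-mouse rate heterogeneity — none
of which the generator emulates.

## Problem sizes and numerical choices

Recovery runs use the study-scale design (120 mice, 21 survey ages) and
200 bootstrap replicates; 200 is where the percentile intervals of
interest stabilise for these data, and the replicate count is a config
field (`BootstrapConfig.n_reps`, default 1000) rather than a constant.
Morris screens use 60–100 trajectories (stabilization is tested by
doubling).  Optimiser tolerances are `xtol = ftol = gtol = 1e-12`
(1e-14 for the three-parameter field fit, which must reproduce
noiseless data to machine precision); ties between equal-cost
multi-starts resolve to the first found.  Degenerate inputs are defined
behaviour: empty surveys raise `InsufficientDataError`, zero-tumor
surveys pin rates to the lower bound, flat palpation series yield
undefined TVDT, and an all-censored survival curve has no median.

## Known limitations

* The FOSL `p1` point estimate is reported but means little; use the
  interval.
* Field-parameter uncertainty enters only through the fixed 5% jitter;
  the bootstrap does not propagate digestion-fit error beyond it.
* The risk grid's "likelihood" is an expectation by default; absolute
  frontier positions (cells needed for a likely tumor) depend on that
  choice and on the cutoff, and only orderings and scalings are treated
  as robust.
* Printed-value reproduction is limited to quantities computable from
  published tables; refits of the original animal data are not
  reproducible from counts alone.
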