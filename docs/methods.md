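# Methods

## The competing-risks model and its estimators

A competing-risks process starts in an initial state and moves, at the event
time `T`, into one of two absorbing states; `X_T ∈ {1, 2}` is the type of
the first event. The cause-specific hazards (CSHs) `α_0j(t)` are the
momentary forces of transition; their cumulatives `A_0j(t)` are what
nonparametric inference targets. The package's estimators share one counting
backbone (per unique observed time: at-risk count `Y`, event counts `d_1`,
`d_2`, censoring count `d_0`) so that the classical identities hold exactly
in finite samples, not just asymptotically:

* Nelson-Aalen: `Â_0j(t) = Σ_{s≤t} d_j(s)/Y(s)`, cumulative variance
  `Σ d_j(s)/Y(s)²` — the simplest of the standard variance estimators;
  pointwise 95% CIs use the log transformation `Â · exp(±1.96·se/Â)`. The
  variance/CI choices are declared, not inferred from any reference output.
* Kaplan-Meier: product-limit over pooled event counts; with the roles of
  event (status 0) and censoring (statuses 1, 2) swapped it estimates the
  censoring survival function.
* Aalen-Johansen: `F̂_j(t) = Σ_{s≤t} Ŝ(s−) · ΔÂ_0j(s)`, with `Ŝ(s−)` the
  left-limit Kaplan-Meier value (1 before the first jump).

Tie convention: at a time carrying both events and censorings, events are
processed first — censored subjects at `t` remain in the risk set for events
at `t`. Evaluation beyond the last jump freezes the curve; nothing is
extrapolated.

## The empirical law and the two-step algorithm

A control dataset defines a discrete probability law: `P(T = s)` is the
all-cause Kaplan-Meier drop at each event time `s`; the probability mass the
KM curve never spends (because of right-censoring) becomes a *tail point
mass* beyond the largest observed time, and draws landing there are always
censored; `P(X_T = 1 | T = s)` is `ΔÂ_01(s)/(ΔÂ_01(s)+ΔÂ_02(s)) =
d_1(s)/(d_1(s)+d_2(s))` — pooled counts at the (rare) times carrying both
causes. Simulation is the two-step algorithm: draw the time from
(masses, tail), then the type from the per-time Bernoulli, then impose an
independent censoring time drawn from the censoring Kaplan-Meier of the
control data.

Design choices made here:

* **Discrete product-integral, not `exp(−A)`.** Survival is reconstructed
  from hazard increments as `S(t) = Π_{s≤t}(1 − ΔA_1(s) − ΔA_2(s))`, which
  makes `build_law` and `law_from_hazards` exact inverses on empirical
  input — the package operates entirely on step functions, and the
  round-trip identity is tested at machine precision.
* **Admissibility.** Transformations and effects can push a pooled
  increment above 1, where no probability law exists. Increments in
  `(1, 1+1e−9]` are clamped (float slack); anything larger raises a named
  error reporting the offending time rather than truncating silently.
* **Transforms act on cumulatives.** Monotone maps with `f(0)=0`
  (`identity`, `x^{1/4}`, `x²`, or user-supplied) are applied to the
  cumulative hazards and increments recovered by differencing, keeping the
  event-time support unchanged; monotonicity guarantees nonnegative
  increments. For cumulative values below 1, `x^{1/4}` amplifies a hazard
  and `x²` shrinks it — the lever the preset scenarios use to show that a
  hazard ratio's meaning depends on its baseline.
* **Tail sentinel.** Tail realisations are `+inf` internally; they lose
  `min(T, C)` to every finite censoring time, so "always censored" needs no
  special branch. Tail subjects receive a censoring draw like everyone else
  and contribute that time as a censored observation.
* **Proper censoring law.** If a censoring survival curve leaves mass
  unspent, a named warning is raised and the remainder is placed just after
  the largest observed time, where it can never censor an observed event
  time. The surrogate cohorts essentially always produce proper censoring
  laws on their own.
* **Event-vs-censoring ties.** A simulated `T = C` counts as an observed
  event, mirroring the estimator-side events-first convention so that
  estimate → simulate → estimate is self-consistent. (Under a continuous
  censoring law such ties have probability zero; the discrete
  implementation must still fix a rule.)
* **Transformed scenarios keep the original support.** Whether a
  transformation should also remap event times is genuinely open; acting on
  the cumulative values over a fixed support is the declared reading.

## Treatment arms: "ideal" Cox models

A scenario specifies log CSH ratios `(β_1, β_2)` and per-cause baseline
transformations. The treatment law scales the (transformed) control
increments by `exp(β_j)` per cause and rebuilds the law by the
product-integral; both arms share the control censoring distribution. With
`β_1 < 0 = β_2` the per-time type-1 probabilities drop uniformly; with
unidirectional `β_2 < β_1 < 0` they rise — the mechanism that can make
cumulative incidence curves cross despite a negative effect of interest,
and what the point-mass diagnostic visualises.

## Cause-specific Cox regression

The partial likelihood for cause `j` treats other-cause events as censored.
Only the single binary group covariate is supported — exactly the trial
design the study evaluates. Ties are handled with Breslow's method: the
discrete laws generate many tied event times, and Breslow's partial
likelihood has a closed form that an independent dense grid search can
maximise, which is how the Newton-Raphson solver is cross-checked (to 1e−4
on every small test fixture). Newton-Raphson starts at 0, converges when
|score| < 1e−8 or the step falls below 1e−10 (max 50 iterations), with
step-halving on any likelihood decrease; the standard error is the inverse
root of the observed information at the maximum. Complete separation (all
target-cause events in one arm) yields a flagged non-converged result, not
a crash. An adapter seam delegates the same fit to lifelines for
cross-validation in tests; lifelines uses Efron ties, so exact agreement is
asserted on tie-free data only. The native implementation is the reference.

Wald machinery: CI = `β̂ ± 1.96·se`; two-sided p-value from the exact normal
survival function; empirical power = share of replicates with `p < 0.05`.

## Scenario studies and aggregation

`run_scenario` simulates `R` trials (default geometry: 500 subjects per
arm), fits both cause-specific models per trial, and aggregates per cause:
mean estimate, *empirical 95% CI* as the 2.5th/97.5th percentiles of the
replicate estimates (linear-interpolation percentiles — the percentile
reading of "empirical CI" is a declared choice and is not silently
switched), Wald coverage of the true `β_j`, and empirical power. Replicates
where a fit fails to converge are counted and excluded; with the preset
event counts they do not occur. Randomness follows a documented spawning
rule — `SeedSequence(master).spawn(...)` per replicate and per scenario — so
every replicate is individually reproducible and a scenario's result does
not depend on which other scenarios run alongside it.

The ten preset scenarios pair `β_1 ∈ {−0.1, −0.3}` with
`β_2 ∈ {0, 0.3, −0.3}` and the baseline transformations above. The
point-mass diagnostic compares per-time masses of the two arms' laws inside
a window (default `[0.07, 5.4]`, trimming the steep extremes of the
observed range; configurable), either for all events or restricted to times
with positive type-1 mass, flagging the arm with strictly larger mass.
`power_curve` repeats a scenario over a grid of per-arm sizes — the
simulation-based sample-size planning tool; it needs no closed-form hazard
assumption, only control-arm data.

## The surrogate control cohort

The original trial's placebo arm (636 patients; 38.2% events of interest,
20.3% competing events, 41.5% censored; all-cause KM spending ≈76% of its
mass; near-linear cumulative CSHs) is not publicly available. The fixtures
module substitutes the simplest generator consistent with every printed
characteristic: constant CSHs `λ_1, λ_2` (exponential event times) with
uniform censoring on a window, default `(2, 6)` years — a modelling choice
loosely mirroring a four-year accrual window followed by two further years
of follow-up; any window may be supplied. Calibration solves
`P(T < C) = 0.585` for the total rate by bisection to 1e−10, with
`E[e^{−λC}] = (e^{−λ c_min} − e^{−λ c_max})/(λ(c_max − c_min))`, and splits
it as `λ_1 = (243/372)·λ_·`. The calibrated total rate is ≈0.23/year and
the model survival at the window end `e^{−λ_· c_max} ≈ 0.25`, matching the
≈24% unspent KM mass.

What the surrogate does *not* emulate: the real arm's covariates, accrual
dynamics, any time-dependence of the hazards, or the exact censoring law.
Scenario-study results computed on it therefore reproduce reference values
approximately — parameter means and coverage closely (they are driven by
the Cox machinery, not the baseline shape), power to within a few
percentage points (it depends on the realised event counts, which the
calibration matches only in expectation). Exact-identity and oracle tests
are independent of the surrogate entirely.

## Problem sizes and numerical notes

The shipped study runs use 1000 replicates of 500 subjects per arm
(seconds per scenario with the vectorised counting-process code); the test
suite uses the same sizes for headline checks and smaller ones (tens to
hundreds of replicates) for structural checks. Large-cohort calibration
checks use n = 100,000. Percentiles, random draws and root finding use
numpy/scipy defaults except where stated. Degenerate inputs (no events of a
cause, all-censored data, empty datasets, empty windows) raise named errors
or return the documented degenerate estimates; these paths are unit-tested.

## Known limitations

* One transient and two absorbing states only; no left truncation,
  time-dependent covariates, or multi-covariate regression.
* No subdistribution-hazard (Fine-Gray) modelling, no Gray's test, no
  smoothing of the per-time type probabilities, no CIF variance bands.
* The empirical law treats the estimated quantities as the truth of the
  simulation; sampling noise of the control cohort propagates into every
  scenario built on it (by design — that is the "empirical" in empirical
  simulation).
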