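# crsim — empirical simulation of competing-risks data

`crsim` is a toolkit for biostatisticians analysing or planning studies with
*competing risks*: time-to-first-event data where the event can be one of two
mutually exclusive types (an event of interest and a competing event, e.g.
cardiovascular death vs death from other causes). It treats the
cause-specific hazards as the generative engine of such data and makes that
view operational — for estimation, for interpretation, and for
simulation-based power calculation.

## The model

For an event time `T` with type `X_T ∈ {1, 2}`, the cause-specific hazards
(CSHs) are

    α_0j(t) dt = P(T ∈ dt, X_T = j | T ≥ t),   j = 1, 2.

Together the CSHs determine everything: all-cause survival
`S(t) = exp(−A_01(t) − A_02(t))` and the cumulative incidence functions
(CIFs) `F_j(t) = ∫_0^t S(u−) α_0j(u) du`. Data arise from a two-step
algorithm: (1) draw `T` from the all-cause distribution with hazard
`α_01 + α_02`; (2) at `T`, draw the type as a Bernoulli with probability
`α_01(T) / (α_01(T) + α_02(T))`.

`crsim` implements the empirical analogue end to end:

* **estimators** — Nelson-Aalen cumulative CSHs (`dA_j = d_j/Y` with
  variance `Σ d_j/Y²` and log-transformed CIs), Kaplan-Meier all-cause and
  censoring survival, Aalen-Johansen CIFs; the finite-sample identities
  (`F_1 + F_2 = 1 − S`, KM = product-integral of pooled NA increments) hold
  to machine precision.
* **lawkit** — any control dataset becomes a discrete *empirical law*:
  event-time masses from the KM drops, a tail point mass for unspent
  probability, per-time type-1 probabilities from the NA increments, plus
  the censoring distribution. Monotone baseline transformations
  (`x ↦ x^{1/4}`, `x ↦ x²`) and proportional effects `exp(β_j)` produce
  treatment-arm laws from "ideal" Cox models.
* **simulate** — the two-step algorithm applied to a law, with independent
  censoring; tail realisations are always censored.
* **coxcs** — cause-specific Cox regression for a binary group covariate
  (other-cause events recoded as censored; Breslow ties; Newton-Raphson).
* **study** — scenario studies over replicated trials (mean log CSH ratios,
  empirical percentile CIs, Wald coverage, empirical power), per-time
  point-mass diagnostics, and power curves for sample-size planning.
* **fixtures** — a calibrated constant-hazard surrogate control cohort
  (exponential event times, uniform censoring) matching a dialysis trial's
  printed placebo-arm characteristics, so everything is runnable without
  external data.

## Worked example

```python
from crsim import TABLE_SCENARIOS, control_cohort, run_scenario

control = control_cohort(seed=1)          # calibrated surrogate, n = 636
res = run_scenario(control, TABLE_SCENARIOS[5], n_replicates=200, seed=3)
```

which prints (via `examples/03_scenario_study.py`):

```
scenario 6: beta1=-0.3, beta2=0.0
  interest  mean -0.300 (true -0.3) emp. 95% CI [-0.51, -0.09] coverage 97.0% power 78.0%
  competing mean +0.003 (true +0.0) emp. 95% CI [-0.30, +0.28] coverage 94.0% power 6.0%
```

Reading: across 200 simulated trials (500 subjects/arm) the mean estimated
log CSH ratio for the event of interest recovers the true `β₁ = −0.3`; the
Wald CIs cover at roughly the nominal 95%; the test for the event of
interest rejects in ~78% of trials while the competing-event test, whose
true effect is null, keeps its ~5% size. The `examples/` directory holds
one narrative script per capability (estimation, law round-trip, scenario
study, point-mass diagnostic, power planning).

A thin CLI mirrors the library:

```sh
crsim fixture --out control.csv --n 636 --seed 1
crsim estimate control.csv --outdir estimates
crsim study run --control control.csv --reps 1000 --seed 1 --out table.csv
```

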