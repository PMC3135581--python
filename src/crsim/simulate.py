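"""Two-step generation of competing-risks data from a discrete law.

Step 1 draws the event time T from the all-cause distribution (support
masses plus the tail point mass; tail realisations are the sentinel +inf).
Step 2 draws the event type at T from a Bernoulli with the law's type-1
probability at that support point. An independent censoring time C is drawn
from the law's censoring distribution; the observed time is min(T, C) with
status = cause if T <= C (ties resolve to the event) and 0 otherwise. Tail
realisations always lose to a finite C, hence are always censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import StepCumulativeHazard, SurvivalCurve
from .lawkit import EmpiricalLaw, Scenario, apply_scenario
from .survdata import CompetingRisksDataset

__all__ = ["TAIL", "SimulationConfig", "draw_event", "simulate_arm", "simulate_trial"]

#: sentinel for event times beyond the largest observed time
TAIL = float("inf")


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducibility contract of a simulated trial: a master seed and the
    per-arm sample sizes. The same (law, config) pair yields a
    bit-identical dataset."""

    seed: int
    n_control: int = 500
    n_treatment: int = 500
    control_label: int = 0
    treatment_label: int = 1


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_events(law: EmpiricalLaw, n: int, rng: np.random.Generator):
    """Vectorised step 1 + step 2: times (TAIL sentinel for the tail atom)
    and causes (0 where the draw landed in the tail)."""
    probs = np.concatenate((law.time_mass, [law.tail_mass]))
    probs = probs / probs.sum()  # remove float slack; sums to 1 by contract
    idx = rng.choice(probs.size, size=n, p=probs)
    in_tail = idx == law.support.size
    times = np.where(in_tail, TAIL, law.support[np.minimum(idx, law.support.size - 1)])
    p1 = np.where(in_tail, 0.0, law.type1_prob[np.minimum(idx, law.support.size - 1)])
    causes = np.where(in_tail, 0, np.where(rng.random(n) < p1, 1, 2))
    return times, causes


def draw_event(law: EmpiricalLaw, rng) -> tuple[float, int | None]:
    """One two-step draw: (event time or the TAIL sentinel, cause 1|2|None).

    Tail realisations carry no cause; in a trial they are always censored.
    """
    t, c = _draw_events(law, 1, _as_rng(rng))
    return (float(t[0]), None if c[0] == 0 else int(c[0]))


def _draw_censoring(law: EmpiricalLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    times, masses = law.censoring_distribution()
    if times.size == 0:
        # no censoring observed at all: nobody is ever censored
        return np.full(n, TAIL)
    masses = masses / masses.sum()
    return times[rng.choice(times.size, size=n, p=masses)]


def simulate_arm(law: EmpiricalLaw, n: int, rng) -> CompetingRisksDataset:
    """Simulate one arm of n subjects from a law.

    Each subject gets an independent (T, cause) from the two-step draw and a
    censoring time C from the law's censoring distribution; the observation
    is (min(T, C), status) with the T = C tie resolved to the event.
    """
    rng = _as_rng(rng)
    times, causes = _draw_events(law, n, rng)
    cens = _draw_censoring(law, n, rng)
    event_observed = times <= cens  # tie goes to the event; TAIL never wins
    observed = np.where(event_observed, times, cens)
    status = np.where(event_observed, causes, 0)
    return CompetingRisksDataset(time=observed, status=status)


def simulate_trial(
    control_hazards: tuple[StepCumulativeHazard, StepCumulativeHazard],
    censoring: SurvivalCurve,
    scenario: Scenario,
    config: SimulationConfig,
) -> CompetingRisksDataset:
    """Simulate a two-arm trial under a scenario.

    The control arm is drawn from the (possibly transformed) control law,
    the treatment arm from the proportionally scaled law; both arms share
    the control censoring distribution. Group labels are attached.
    """
    control_law, treatment_law = apply_scenario(control_hazards, censoring, scenario)
    rng = _as_rng(config.seed)
    control = simulate_arm(control_law, config.n_control, rng)
    treatment = simulate_arm(treatment_law, config.n_treatment, rng)
    return CompetingRisksDataset(
        time=np.concatenate((control.time, treatment.time)),
        status=np.concatenate((control.status, treatment.status)),
        group=np.concatenate(
            (
                np.full(config.n_control, config.control_label),
                np.full(config.n_treatment, config.treatment_label),
            )
        ),
    )
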