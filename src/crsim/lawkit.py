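"""Discrete simulable laws built from competing-risks estimators.

The "empirical law" of a dataset is the probability measure its step-function
estimators define: the all-cause Kaplan-Meier drops give the event-time
masses, a tail point mass beyond the largest observed event time absorbs the
probability the Kaplan-Meier curve never spends (realisations landing there
are always censored), and the Nelson-Aalen increments give, per event time,
the binomial probability that the event is of type 1. The censoring survival
function of the same data closes the law so new right-censored samples can be
drawn.

Treatment arms are derived from "ideal" proportional cause-specific hazards:
the control increments (optionally after a monotone transformation of the
cumulative hazards) are scaled by exp(beta_j) per cause and the law is
rebuilt by the discrete product-integral.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import (
    InadmissibleIncrementError,
    NoEventsError,
    UnspentCensoringMassWarning,
)
from .estimators import StepCumulativeHazard, SurvivalCurve, CIFEstimate, kaplan_meier, nelson_aalen
from .survdata import CompetingRisksDataset

__all__ = [
    "EmpiricalLaw",
    "Scenario",
    "TRANSFORMS",
    "build_law",
    "law_from_hazards",
    "apply_scenario",
]

_MASS_TOL = 1e-12
_CLAMP_SLACK = 1e-9

#: named monotone maps on cumulative-hazard values, all fixing 0
TRANSFORMS: dict[str, Callable[[float], float]] = {
    "identity": lambda x: x,
    "fourth-root": lambda x: x**0.25,
    "square": lambda x: x**2,
}


def resolve_transform(spec) -> Callable[[float], float]:
    if callable(spec):
        return spec
    try:
        return TRANSFORMS[spec]
    except KeyError:
        raise ValueError(
            f"unknown transform {spec!r}; known: {sorted(TRANSFORMS)}"
        ) from None


@dataclass(frozen=True)
class EmpiricalLaw:
    """Discrete two-cause event-time law plus censoring distribution.

    ``support`` holds the strictly increasing event times carrying positive
    (or structurally zero) mass; ``time_mass[k]`` is P(T = support[k]);
    ``tail_mass`` is the probability of landing beyond the largest observed
    time (always censored in simulation); ``type1_prob[k]`` is the
    probability that the event at ``support[k]`` is of type 1.
    """

    support: np.ndarray
    time_mass: np.ndarray
    tail_mass: float
    type1_prob: np.ndarray
    censoring: SurvivalCurve

    def __post_init__(self):
        sup = np.asarray(self.support, dtype=float)
        tm = np.asarray(self.time_mass, dtype=float)
        p1 = np.asarray(self.type1_prob, dtype=float)
        if not (sup.shape == tm.shape == p1.shape):
            raise ValueError("support, time_mass and type1_prob must align")
        if sup.size and (np.any(np.diff(sup) <= 0) or sup[0] <= 0):
            raise ValueError("support must be strictly increasing and positive")
        if np.any(tm < -_MASS_TOL) or self.tail_mass < -_MASS_TOL:
            raise ValueError("masses must be nonnegative")
        total = float(np.sum(tm) + self.tail_mass)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses must sum to 1, got {total}")
        if np.any(p1 < -_MASS_TOL) or np.any(p1 > 1 + _MASS_TOL):
            raise ValueError("type1_prob must lie in [0, 1]")
        object.__setattr__(self, "support", sup)
        object.__setattr__(self, "time_mass", np.clip(tm, 0.0, None))
        object.__setattr__(self, "type1_prob", np.clip(p1, 0.0, 1.0))

    # -- implied quantities -------------------------------------------------

    def survival(self, t):
        """Implied all-cause survival P(T > t) of the discrete law."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.support, t, side="right")
        cum = np.concatenate(([0.0], np.cumsum(self.time_mass)))
        out = 1.0 - cum[idx]
        return out if out.ndim else float(out)

    def cif(self, cause: int) -> CIFEstimate:
        """Implied cumulative incidence of one cause."""
        if cause not in (1, 2):
            raise ValueError("cause must be 1 or 2")
        p = self.type1_prob if cause == 1 else 1.0 - self.type1_prob
        return CIFEstimate(
            jump_times=self.support,
            values=np.cumsum(self.time_mass * p),
            cause=cause,
        )

    def censoring_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete censoring law (times, masses) implied by the censoring
        survival curve.

        If the curve leaves mass unspent, that mass is placed at a point just
        after the largest observed time (with a named warning) so the
        censoring law is proper.
        """
        times = self.censoring.jump_times
        masses = self.censoring.drops()
        leftover = self.censoring.final_value
        if leftover > _MASS_TOL:
            tmax = self.censoring.tmax
            if tmax is None:
                tmax = float(times[-1]) if times.size else float(self.support[-1])
            warnings.warn(
                f"censoring curve leaves {leftover:.4g} probability unspent; "
                f"placing it just after the largest observed time {tmax:.6g}",
                UnspentCensoringMassWarning,
            )
            beyond = tmax * (1 + 1e-9) + 1e-12
            times = np.concatenate((times, [beyond]))
            masses = np.concatenate((masses, [leftover]))
        return times, masses

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "support": self.support.tolist(),
            "time_mass": self.time_mass.tolist(),
            "tail_mass": self.tail_mass,
            "type1_prob": self.type1_prob.tolist(),
            "censoring": {
                "jump_times": self.censoring.jump_times.tolist(),
                "values": self.censoring.values.tolist(),
                "tmax": self.censoring.tmax,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmpiricalLaw":
        return cls(
            support=np.asarray(d["support"], dtype=float),
            time_mass=np.asarray(d["time_mass"], dtype=float),
            tail_mass=float(d["tail_mass"]),
            type1_prob=np.asarray(d["type1_prob"], dtype=float),
            censoring=SurvivalCurve(
                jump_times=np.asarray(d["censoring"]["jump_times"], dtype=float),
                values=np.asarray(d["censoring"]["values"], dtype=float),
                role="censoring",
                tmax=d["censoring"].get("tmax"),
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "EmpiricalLaw":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: cause-specific log hazard ratios and
    monotone transformations of the control cumulative hazards.

    ``beta1``/``beta2`` are log cause-specific hazard ratios (treatment vs
    control); ``transform1``/``transform2`` name (or supply) monotone maps
    with f(0) = 0 applied to the control cumulative hazards of causes 1 and 2
    before the proportional effects act.
    """

    beta1: float
    beta2: float
    transform1: str | Callable[[float], float] = "identity"
    transform2: str | Callable[[float], float] = "identity"
    n_control: int = 500
    n_treatment: int = 500
    name: str | None = None

    def __post_init__(self):
        resolve_transform(self.transform1)
        resolve_transform(self.transform2)
        if self.n_control < 1 or self.n_treatment < 1:
            raise ValueError("arm sizes must be positive")

    @property
    def hazard_ratio1(self) -> float:
        return float(np.exp(self.beta1))

    @property
    def hazard_ratio2(self) -> float:
        return float(np.exp(self.beta2))

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            beta1=float(d["beta1"]),
            beta2=float(d["beta2"]),
            transform1=d.get("transform1", "identity"),
            transform2=d.get("transform2", "identity"),
            n_control=int(d.get("n_control", 500)),
            n_treatment=int(d.get("n_treatment", 500)),
            name=d.get("name"),
        )


def build_law(data: CompetingRisksDataset) -> EmpiricalLaw:
    """Empirical law of a dataset.

    Event-time masses are the all-cause Kaplan-Meier drops, the tail mass is
    the Kaplan-Meier value at the last event time, the per-time type-1
    probability is ``d1/(d1+d2)``, and the censoring distribution is the
    censoring-role Kaplan-Meier of the same data. Identical (by the discrete
    product-integral identity) to ``law_from_hazards`` on the dataset's own
    Nelson-Aalen estimators, which is how it is computed.
    """
    if not np.any(data.status > 0):
        raise NoEventsError("empirical law undefined: dataset has no events")
    return law_from_hazards(
        nelson_aalen(data, 1), nelson_aalen(data, 2), kaplan_meier(data, "censoring")
    )


def law_from_hazards(
    cum_haz1: StepCumulativeHazard,
    cum_haz2: StepCumulativeHazard,
    censoring: SurvivalCurve,
) -> EmpiricalLaw:
    """Reconstruct the discrete law from a pair of cumulative cause-specific
    hazards via the product-integral:

    ``S(t) = prod_{s<=t} (1 - dA1(s) - dA2(s))``,
    ``P(T = s) = S(s-) * (dA1(s) + dA2(s))``, tail mass ``S(last jump)``,
    ``P(type 1 | T = s) = dA1(s) / (dA1(s) + dA2(s))``.

    Raises :class:`InadmissibleIncrementError` when a pooled increment
    exceeds 1 beyond float slack (1e-9), signalling that a transformation or
    effect pushed the discrete hazards outside probability range.
    """
    support = np.union1d(cum_haz1.jump_times, cum_haz2.jump_times)
    if support.size == 0:
        raise NoEventsError("hazards carry no jumps; law undefined")
    d1 = np.zeros(support.size)
    d2 = np.zeros(support.size)
    d1[np.searchsorted(support, cum_haz1.jump_times)] = cum_haz1.increments
    d2[np.searchsorted(support, cum_haz2.jump_times)] = cum_haz2.increments
    pooled = d1 + d2
    over = pooled - 1.0
    if np.any(over > _CLAMP_SLACK):
        k = int(np.argmax(over))
        raise InadmissibleIncrementError(float(support[k]), float(pooled[k]))
    pooled = np.minimum(pooled, 1.0)
    surv = np.cumprod(1.0 - pooled)
    s_minus = np.concatenate(([1.0], surv[:-1]))
    time_mass = s_minus * pooled
    with np.errstate(invalid="ignore"):
        type1 = np.where(pooled > 0, d1 / np.where(pooled > 0, pooled, 1.0), 0.0)
    return EmpiricalLaw(
        support=support,
        time_mass=time_mass,
        tail_mass=float(surv[-1]),
        type1_prob=type1,
        censoring=censoring,
    )


def apply_scenario(
    control_hazards: tuple[StepCumulativeHazard, StepCumulativeHazard],
    censoring: SurvivalCurve,
    scenario: Scenario,
) -> tuple[EmpiricalLaw, EmpiricalLaw]:
    """Build the (control, treatment) law pair of a scenario.

    Control hazards are the scenario's transforms applied to the cumulative
    control hazards (then differenced on the same support); treatment
    hazards additionally scale each cause's increments by exp(beta_j). Both
    arms share the control censoring law.
    """
    a1, a2 = control_hazards
    f1 = resolve_transform(scenario.transform1)
    f2 = resolve_transform(scenario.transform2)
    base1 = a1.transformed(f1)
    base2 = a2.transformed(f2)
    control = law_from_hazards(base1, base2, censoring)
    treatment = law_from_hazards(
        base1.scaled(scenario.hazard_ratio1),
        base2.scaled(scenario.hazard_ratio2),
        censoring,
    )
    return control, treatment
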