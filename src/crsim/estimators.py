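"""Nonparametric estimation for competing risks.

Implements the three classical step-function estimators on a shared counting
backbone so that their finite-sample identities hold exactly, not just
asymptotically:

* Nelson-Aalen cumulative cause-specific hazards
  ``A_j(t) = sum_{s<=t} d_j(s) / Y(s)``,
* Kaplan-Meier all-cause survival
  ``S(t) = prod_{s<=t} (1 - d(s)/Y(s))`` (and, with the roles of event and
  censoring swapped, the censoring survival function), and
* the Aalen-Johansen plug-in cumulative incidence
  ``F_j(t) = sum_{s<=t} S(s-) * dA_j(s)``.

Here ``d_j(s)`` counts cause-``j`` events at time ``s`` and ``Y(s)`` the
subjects still at risk just before ``s``. At a time carrying both events and
censorings, events are processed first: censored subjects at ``s`` remain in
the risk set for events at ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError
from .survdata import CompetingRisksDataset

__all__ = [
    "StepCumulativeHazard",
    "SurvivalCurve",
    "CIFEstimate",
    "nelson_aalen",
    "kaplan_meier",
    "aalen_johansen",
    "risk_table",
]

_Z95 = 1.96


def _step_eval(jump_times: np.ndarray, cumvals: np.ndarray, t, before: float):
    """Right-continuous step evaluation, frozen at the last jump."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(jump_times, t, side="right") - 1
    out = np.where(idx >= 0, np.concatenate(([before], cumvals))[idx + 1], before)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StepCumulativeHazard:
    """Right-continuous step estimate of a cumulative cause-specific hazard.

    ``increments[k]`` is the jump ``dA_j`` at ``jump_times[k]``;
    ``variances[k]`` is the *cumulative* variance estimate
    ``sum_{s<=t_k} d_j(s)/Y(s)^2``.
    """

    jump_times: np.ndarray
    increments: np.ndarray
    variances: np.ndarray
    cause: int

    def __post_init__(self):
        jt = np.asarray(self.jump_times, dtype=float)
        inc = np.asarray(self.increments, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        if not (jt.shape == inc.shape == var.shape):
            raise ValueError("jump_times, increments and variances must align")
        if jt.size and (np.any(np.diff(jt) <= 0) or jt[0] <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        if np.any(inc < 0) or np.any(var < 0):
            raise ValueError("increments and variances must be nonnegative")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "increments", inc)
        object.__setattr__(self, "variances", var)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative hazard value at each jump time."""
        return np.cumsum(self.increments)

    def __call__(self, t):
        return _step_eval(self.jump_times, self.cumulative, t, before=0.0)

    def variance_at(self, t):
        return _step_eval(self.jump_times, self.variances, t, before=0.0)

    def confidence_interval(self, t=None) -> pd.DataFrame:
        """Pointwise log-transformed 95% CI, ``A * exp(±1.96*se/A)``.

        At points with ``A = 0`` the interval is the degenerate ``[0, 0]``.
        """
        t = self.jump_times if t is None else np.atleast_1d(np.asarray(t, dtype=float))
        a = np.atleast_1d(self(t))
        se = np.sqrt(np.atleast_1d(self.variance_at(t)))
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.exp(_Z95 * np.where(a > 0, se / a, 0.0))
        lower = np.where(a > 0, a / factor, 0.0)
        upper = np.where(a > 0, a * factor, 0.0)
        return pd.DataFrame(
            {"time": t, "estimate": a, "variance": se**2, "lower": lower, "upper": upper}
        )

    def transformed(self, fn) -> "StepCumulativeHazard":
        """Apply a monotone map with ``fn(0)=0`` to the cumulative values and
        recover increments by differencing (support unchanged).

        Variances are not propagated through the transform; they are reset to
        zero because the result describes a constructed truth, not an estimate.
        """
        new_cum = np.asarray([fn(v) for v in self.cumulative], dtype=float)
        inc = np.diff(np.concatenate(([0.0], new_cum)))
        return StepCumulativeHazard(
            jump_times=self.jump_times,
            increments=inc,
            variances=np.zeros_like(inc),
            cause=self.cause,
        )

    def scaled(self, factor: float) -> "StepCumulativeHazard":
        """Multiply every increment by a positive factor (proportional
        cause-specific hazards, factor = exp(beta))."""
        return StepCumulativeHazard(
            jump_times=self.jump_times,
            increments=self.increments * factor,
            variances=np.zeros_like(self.increments),
            cause=self.cause,
        )

    def to_frame(self) -> pd.DataFrame:
        return self.confidence_interval()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous, nonincreasing step function starting at 1.

    ``role`` is ``"event"`` for P(T > t) or ``"censoring"`` for the censoring
    survival function P(C > t). ``tmax`` records the largest observed time in
    the data the curve came from (event or censored), used when unspent
    censoring mass must be placed beyond the observations.
    """

    jump_times: np.ndarray
    values: np.ndarray
    role: str = "event"
    tmax: float | None = None

    def __post_init__(self):
        jt = np.asarray(self.jump_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if jt.shape != v.shape:
            raise ValueError("jump_times and values must align")
        if jt.size and (np.any(np.diff(jt) <= 0) or jt[0] <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12) or np.any(np.diff(v) > 1e-15):
            raise ValueError("values must be nonincreasing within [0, 1]")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def __call__(self, t):
        return _step_eval(self.jump_times, self.values, t, before=1.0)

    def left_limit(self, t):
        """S(t-): the value strictly before t (1 before the first jump)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left") - 1
        out = np.where(idx >= 0, np.concatenate(([1.0], self.values))[idx + 1], 1.0)
        return out if out.ndim else float(out)

    @property
    def final_value(self) -> float:
        return float(self.values[-1]) if self.values.size else 1.0

    def drops(self) -> np.ndarray:
        """Probability mass spent at each jump time."""
        return -np.diff(np.concatenate(([1.0], self.values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times, "estimate": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CIFEstimate:
    """Nondecreasing cumulative incidence step function starting at 0."""

    jump_times: np.ndarray
    values: np.ndarray
    cause: int

    def __post_init__(self):
        jt = np.asarray(self.jump_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if jt.shape != v.shape:
            raise ValueError("jump_times and values must align")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12) or np.any(np.diff(v) < -1e-15):
            raise ValueError("values must be nondecreasing within [0, 1]")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        return _step_eval(self.jump_times, self.values, t, before=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times, "estimate": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def risk_table(data: CompetingRisksDataset) -> pd.DataFrame:
    """Per unique observed time: at-risk count ``Y`` and counts ``d0`` (newly
    censored), ``d1``, ``d2`` (events by cause)."""
    if len(data) == 0:
        raise EmptyDatasetError("risk table of an empty dataset")
    times = np.unique(data.time)
    # Y(s) = # subjects with observed time >= s; events at s precede censorings
    order = np.searchsorted(times, data.time)
    n = len(data)
    counts = {s: np.bincount(order[data.status == s], minlength=times.size) for s in (0, 1, 2)}
    total_at = counts[0] + counts[1] + counts[2]
    at_risk = n - np.concatenate(([0], np.cumsum(total_at)[:-1]))
    return pd.DataFrame(
        {
            "time": times,
            "at_risk": at_risk,
            "d0": counts[0],
            "d1": counts[1],
            "d2": counts[2],
        }
    )


def nelson_aalen(data: CompetingRisksDataset, cause: int) -> StepCumulativeHazard:
    """Nelson-Aalen estimator of the cumulative cause-specific hazard.

    Jumps by ``d_j(s)/Y(s)`` at each observed cause-``j`` event time; the
    cumulative variance adds ``d_j(s)/Y(s)^2`` per jump.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    tab = risk_table(data)
    d = tab[f"d{cause}"].to_numpy()
    keep = d > 0
    y = tab["at_risk"].to_numpy()[keep]
    dj = d[keep]
    return StepCumulativeHazard(
        jump_times=tab["time"].to_numpy()[keep],
        increments=dj / y,
        variances=np.cumsum(dj / y**2),
        cause=cause,
    )


def kaplan_meier(data: CompetingRisksDataset, role: str = "event") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``role="event"`` estimates all-cause survival P(T > t), pooling causes 1
    and 2; ``role="censoring"`` swaps the roles of event (status 0) and
    censoring (statuses 1, 2) to estimate the censoring survival function.
    """
    if role not in ("event", "censoring"):
        raise ValueError("role must be 'event' or 'censoring'")
    tab = risk_table(data)
    d = (
        (tab["d1"] + tab["d2"]).to_numpy()
        if role == "event"
        else tab["d0"].to_numpy()
    )
    keep = d > 0
    y = tab["at_risk"].to_numpy()[keep]
    values = np.cumprod(1.0 - d[keep] / y)
    return SurvivalCurve(
        jump_times=tab["time"].to_numpy()[keep],
        values=values,
        role=role,
        tmax=float(tab["time"].iloc[-1]),
    )


def aalen_johansen(data: CompetingRisksDataset, cause: int) -> CIFEstimate:
    """Aalen-Johansen plug-in estimator of the cumulative incidence function,
    ``F_j(t) = sum_{s<=t} S(s-) * dA_j(s)`` with S the all-cause
    Kaplan-Meier left limit.

    Satisfies ``F_1(t) + F_2(t) = 1 - S(t)`` exactly at every t.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    tab = risk_table(data)
    d_all = (tab["d1"] + tab["d2"]).to_numpy()
    y = tab["at_risk"].to_numpy()
    surv = np.cumprod(1.0 - d_all / y)
    s_minus = np.concatenate(([1.0], surv[:-1]))
    dj = tab[f"d{cause}"].to_numpy()
    jumps = s_minus * dj / y
    keep = d_all > 0  # CIFs can only move at event times
    return CIFEstimate(
        jump_times=tab["time"].to_numpy()[keep],
        values=np.cumsum(jumps)[keep],
        cause=cause,
    )
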