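"""Cause-specific Cox regression for a binary group covariate.

A Cox model for one cause-specific hazard is fitted by recoding the other
cause's events as censored and maximising the Breslow partial likelihood

    l(b) = sum_s [ m1(s) * b - d(s) * log(Y0(s) + Y1(s) * exp(b)) ]

over the single coefficient b, where at each event time s the counts are
d(s) events in total, m1(s) of them in the treatment arm, and Y0(s), Y1(s)
subjects at risk per arm. Newton-Raphson with step-halving solves the score
equation; the standard error comes from the observed information at the
maximum. Only the single binary covariate of a two-arm trial is supported —
exactly the design the simulation study evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConvergenceError, EmptyDatasetError, NoEventsError, ValidationError
from .survdata import CompetingRisksDataset

__all__ = ["CoxFit", "fit_cause_specific", "breslow_loglik", "fit_with_lifelines"]

_Z95 = 1.96
_SCORE_TOL = 1e-8
_STEP_TOL = 1e-10
_MAX_ITER = 50


@dataclass(frozen=True)
class CoxFit:
    """Result of one cause-specific Cox fit.

    ``coefficient`` is the log cause-specific hazard ratio (treatment vs
    control); ``wald_ci`` is coefficient ± 1.96·se; ``p_value`` the two-sided
    Wald p. ``converged`` is False on complete separation (all target-cause
    events in one arm), in which case the numeric fields are NaN.
    """

    cause: int
    coefficient: float
    standard_error: float
    wald_ci: tuple[float, float]
    p_value: float
    converged: bool
    iterations: int
    n_events: int

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coefficient))


def _breslow_counts(data: CompetingRisksDataset, cause: int):
    """Per unique target-cause event time: d, m1, Y0, Y1."""
    if data.group is None:
        raise ValidationError("cause-specific Cox fit needs a group column")
    event = data.status == cause  # other-cause events act as censorings
    etimes = np.unique(data.time[event])
    if etimes.size == 0:
        raise NoEventsError(f"no cause-{cause} events; fit undefined")
    d = np.zeros(etimes.size)
    m1 = np.zeros(etimes.size)
    idx = np.searchsorted(etimes, data.time[event])
    np.add.at(d, idx, 1.0)
    np.add.at(m1, idx[data.group[event] == 1], 1.0)
    # risk counts per arm: number with observed time >= each event time
    t1 = np.sort(data.time[data.group == 1])
    t0 = np.sort(data.time[data.group == 0])
    y1 = t1.size - np.searchsorted(t1, etimes, side="left")
    y0 = t0.size - np.searchsorted(t0, etimes, side="left")
    return d, m1, y0.astype(float), y1.astype(float)


def breslow_loglik(data: CompetingRisksDataset, cause: int, beta) -> np.ndarray:
    """Breslow log partial likelihood at one or many coefficient values.

    Exposed so an independent maximiser (e.g. a dense grid search) can
    cross-check the Newton-Raphson solution.
    """
    d, m1, y0, y1 = _breslow_counts(data, cause)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eb = np.exp(beta)[:, None]
    ll = (m1 * beta[:, None] - d * np.log(y0 + y1 * eb)).sum(axis=1)
    return ll if ll.size > 1 else float(ll[0])


def fit_cause_specific(data: CompetingRisksDataset, cause: int) -> CoxFit:
    """Fit the cause-specific Cox model for one cause.

    Events of the other cause are treated as censorings; Breslow tie
    handling; Newton-Raphson from 0 with step-halving on likelihood
    decrease. Complete separation (every target-cause event in one arm)
    yields a named non-converged result rather than an exception.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    if len(data) == 0:
        raise EmptyDatasetError("cannot fit on an empty dataset")
    d, m1, y0, y1 = _breslow_counts(data, cause)
    n_events = int(d.sum())

    # complete separation: the score cannot vanish at finite beta
    if m1.sum() == 0 or m1.sum() == d.sum():
        return CoxFit(
            cause=cause,
            coefficient=float("nan"),
            standard_error=float("nan"),
            wald_ci=(float("nan"), float("nan")),
            p_value=float("nan"),
            converged=False,
            iterations=0,
            n_events=n_events,
        )

    def ll_score_info(b):
        eb = np.exp(b)
        denom = y0 + y1 * eb
        pi = y1 * eb / denom
        ll = float(np.sum(m1 * b - d * np.log(denom)))
        score = float(np.sum(m1 - d * pi))
        info = float(np.sum(d * pi * (1.0 - pi)))
        return ll, score, info

    beta = 0.0
    ll, score, info = ll_score_info(beta)
    converged = False
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        if abs(score) < _SCORE_TOL:
            converged = True
            break
        step = score / info
        # step-halving: never accept a likelihood decrease
        for _ in range(30):
            new_ll, new_score, new_info = ll_score_info(beta + step)
            if new_ll >= ll - 1e-14:
                break
            step /= 2.0
        beta += step
        ll, score, info = new_ll, new_score, new_info
        if abs(step) < _STEP_TOL:
            converged = abs(score) < 1e-4  # tiny step with flat score: done
            break
    else:
        iterations = _MAX_ITER
    if abs(score) < _SCORE_TOL:
        converged = True
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge after {iterations} iterations "
            f"(score {score:.3g})"
        )
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    return CoxFit(
        cause=cause,
        coefficient=float(beta),
        standard_error=se,
        wald_ci=(float(beta - _Z95 * se), float(beta + _Z95 * se)),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        converged=True,
        iterations=iterations,
        n_events=n_events,
    )


def fit_with_lifelines(data: CompetingRisksDataset, cause: int):
    """Adapter seam: the same cause-specific fit delegated to lifelines'
    CoxPHFitter, for cross-validation of the native fit in tests. lifelines
    handles ties with Efron's method, so agreement with the native Breslow
    fit is exact only on tie-free data. Imported lazily; lifelines is a
    test-only dependency."""
    from lifelines import CoxPHFitter  # noqa: PLC0415

    df = data.to_frame()[["time", "status", "group"]].copy()
    df["event"] = (df["status"] == cause).astype(int)
    df = df.drop(columns="status")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.params_["group"]), float(cph.standard_errors_["group"])
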