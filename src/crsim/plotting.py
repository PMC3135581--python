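"""Plotting helpers: cumulative cause-specific hazard panels and the
point-mass bar diagnostic. Thin matplotlib wrappers; styling is minimal."""

from __future__ import annotations

import numpy as np

from .estimators import StepCumulativeHazard
from .study import PointMassComparison

__all__ = ["plot_cumulative_hazards", "plot_point_masses"]


def plot_cumulative_hazards(
    hazards: list[StepCumulativeHazard], labels=None, ax=None, ci: bool = True
):
    """Step plots of cumulative cause-specific hazards with pointwise
    log-transformed 95% confidence intervals."""
    import matplotlib.pyplot as plt  # noqa: PLC0415

    if ax is None:
        _, ax = plt.subplots()
    labels = labels or [f"cause {h.cause}" for h in hazards]
    for h, lab in zip(hazards, labels):
        t = np.concatenate(([0.0], h.jump_times))
        a = np.concatenate(([0.0], h.cumulative))
        ax.step(t, a, where="post", label=lab)
        if ci and h.variances.any():
            band = h.confidence_interval()
            ax.step(band["time"], band["lower"], where="post", lw=0.6, alpha=0.5)
            ax.step(band["time"], band["upper"], where="post", lw=0.6, alpha=0.5)
    ax.set_xlabel("time")
    ax.set_ylabel("cumulative cause-specific hazard")
    ax.legend()
    return ax


def plot_point_masses(cmp: PointMassComparison, ax=None):
    """Mirror-bar plot of the two arms' event-time point masses: control
    below the axis, treatment above; the arm with strictly larger mass at a
    time is drawn black, the other grey."""
    import matplotlib.pyplot as plt  # noqa: PLC0415

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    colors_c = np.where(cmp.control_larger, "black", "0.6")
    colors_t = np.where(cmp.treatment_larger, "black", "0.6")
    width = np.median(np.diff(cmp.times)) * 0.8 if cmp.times.size > 1 else 0.01
    ax.bar(cmp.times, -cmp.mass_control, width=width, color=colors_c)
    ax.bar(cmp.times, cmp.mass_treatment, width=width, color=colors_t)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("time")
    ax.set_ylabel("point mass (control below, treatment above)")
    ax.set_title(f"event-time point masses ({cmp.restriction})")
    return ax
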