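"""Point-mass diagnostic for a unidirectional-effect scenario.

With beta2 < beta1 < 0 all events happen later under treatment (step 1 of
the two-step algorithm), yet the binomial type-1 probabilities rise (step 2),
so the cumulative incidence of interest can eventually cross. The per-time
point-mass comparison makes this visible: flags marking the arm with larger
mass migrate from control to treatment over time.
"""

from crsim import (
    TABLE_SCENARIOS,
    apply_scenario,
    control_cohort,
    kaplan_meier,
    nelson_aalen,
    point_mass_comparison,
)

control = control_cohort(seed=1)
hazards = (nelson_aalen(control, 1), nelson_aalen(control, 2))
censoring = kaplan_meier(control, "censoring")
scen5 = TABLE_SCENARIOS[4]  # beta1=-0.1, beta2=-0.3, opposite baseline transforms
ctrl_law, treat_law = apply_scenario(hazards, censoring, scen5)

cmp = point_mass_comparison(ctrl_law, treat_law, window=(0.07, 5.4), restriction="type1")
k = cmp.times.size // 3
print(f"type-1 event times in window: {cmp.times.size}")
print(f"treatment-larger share, earliest third: {cmp.treatment_larger[:k].mean():.2f}")
print(f"treatment-larger share, latest third:   {cmp.treatment_larger[-k:].mean():.2f}")
print(
    "\nThe treatment arm's type-1 mass dominates increasingly at later times "
    "- the mechanism behind crossing cumulative incidence curves despite a "
    "negative log hazard ratio of interest."
)
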