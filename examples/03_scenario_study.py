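"""A two-scenario simulation study.

Imposes proportional cause-specific treatment effects on the control law
(an 'ideal' Cox data-generating mechanism), simulates 200 two-arm trials of
500 subjects per arm for each scenario, fits cause-specific Cox models per
trial and aggregates mean log hazard ratios, empirical CIs, Wald coverage
and empirical power.
"""

from crsim import TABLE_SCENARIOS, control_cohort, run_scenario

control = control_cohort(seed=1)
for scen in (TABLE_SCENARIOS[0], TABLE_SCENARIOS[5]):  # beta1 = -0.1 and -0.3
    res = run_scenario(control, scen, n_replicates=200, seed=3)
    print(f"scenario {scen.name}: beta1={scen.beta1}, beta2={scen.beta2}")
    for label, m, truth in (("interest", res.cause1, scen.beta1),
                            ("competing", res.cause2, scen.beta2)):
        print(
            f"  {label:9s} mean {m.mean_estimate:+.3f} (true {truth:+.1f}) "
            f"emp. 95% CI [{m.empirical_ci[0]:+.2f}, {m.empirical_ci[1]:+.2f}] "
            f"coverage {m.coverage:.1f}% power {m.empirical_power:.1f}%"
        )
print(
    "\nCoverage sits near the nominal 95%; power for the event of interest "
    "grows with |beta1|, while the competing-event test keeps its ~5% size "
    "when beta2 = 0."
)
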