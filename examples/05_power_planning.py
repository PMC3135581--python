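"""Simulation-based power planning.

Given control-arm data and an assumed treatment effect, empirical power at
candidate sample sizes comes from simulating trials and counting Wald
rejections - no closed-form hazard shape is needed.
"""

from crsim import Scenario, control_cohort, power_curve

control = control_cohort(seed=1)
scenario = Scenario(beta1=-0.3, beta2=0.0)
curve = power_curve(control, scenario, n_grid=[250, 500, 1000], n_replicates=200, seed=4)
print(curve[["n_per_arm", "power1", "power1_se", "power2", "power2_se"]].to_string(index=False))
print(
    "\npower1 is the rejection rate for the event of interest (grows with n); "
    "power2 estimates the competing test's size, staying near 5% since "
    "beta2 = 0."
)
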