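"""From data to a simulable law and back.

Builds the discrete empirical law of a control cohort (event-time masses
from the Kaplan-Meier drops, a tail point mass for the unspent probability,
per-time type-1 probabilities from the Nelson-Aalen increments), simulates a
large arm from it, and shows that re-estimation recovers the law's implied
cumulative incidence functions.
"""

import numpy as np

from crsim import aalen_johansen, build_law, control_cohort, simulate_arm

data = control_cohort(seed=1)
law = build_law(data)
print(f"support points: {law.support.size}")
print(f"tail mass (probability beyond the last event time): {law.tail_mass:.3f}")
print(f"event-time mass spent: {100 * (1 - law.tail_mass):.1f}%")

sim = simulate_arm(law, 50_000, np.random.default_rng(2))
grid = law.support
for cause in (1, 2):
    sup = np.max(np.abs(aalen_johansen(sim, cause)(grid) - law.cif(cause)(grid)))
    print(f"cause {cause}: sup |estimated CIF - law CIF| = {sup:.4f}")
print(
    "\nSmall sup-distances confirm the proof of concept: simulating from the "
    "empirical law reproduces the quantities it was built from."
)
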