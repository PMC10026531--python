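"""Compare depot initiation strategies against the therapeutic window.

Simulates the first two monthly 400-mg injections for a virtual population,
with and without the recommended 14 days of 15-mg oral supplementation, and
reports when each median profile first enters the therapeutic window.
"""

import numpy as np

from aompk import TherapeuticWindow, simulate_scenario, window_coverage
from aompk.population import PopulationSpec, generate_virtual_population

window = TherapeuticWindow(lower=94.0, upper=534.0)
pop = generate_virtual_population(PopulationSpec(n=1000, em_fraction=1.0),
                                  np.random.default_rng(2))
grid = np.arange(0.0, 57.0)

for scheme in ("aom_alone", "aom_plus_oral_initiation"):
    summary = simulate_scenario(pop, scheme, grid, rng=np.random.default_rng(3))
    cov = window_coverage(summary, window)
    med14 = summary.table["p50"].iloc[14]
    print(f"{scheme:26s}  first day in window: {cov.first_day_in_window:4.0f}   "
          f"median day 14: {med14:6.1f} ng/mL   "
          f"fraction of days in window: {cov.fraction_in_window:.2f}")

print()
print("Depot alone needs several days to reach the window; the oral")
print("supplementation keeps the median inside it from the first day.")
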