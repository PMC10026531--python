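"""Model evaluation on a synthetic sparse study: VPC and %PPE statistics.

Simulates a phase-3-like sparse-sampling study from the model, then (a)
runs the visual predictive check, which re-simulates the design and checks
that observed concentration percentiles sit inside the simulated bands, and
(b) computes the percent population prediction errors against the
typical-subject predictions, applying the external-validation rules
(|median %PPE| <= 10 and median |%PPE| < 40).
"""

import numpy as np

from aompk import pk_vpc, population_prediction_errors, population_predictions
from aompk.synthetic import generate_pk_trial, sparse_phase3_design

df, _ = generate_pk_trial(sparse_phase3_design(n=80, n_doses=3),
                          rng=np.random.default_rng(7))

vpc = pk_vpc(df, n_reps=200, rng=np.random.default_rng(8))
print("VPC (time since previous dose, h -> observed vs simulated median):")
for _, row in vpc.table.iterrows():
    print(f"  t ~{row['t_mid']:6.0f} h   obs p50 {row['obs_p50']:7.1f}   "
          f"sim p50 {row['sim_p50_med']:7.1f} "
          f"[{row['sim_p50_lo']:6.1f}, {row['sim_p50_hi']:6.1f}]")
print(f"band coverage across percentiles/bins: {vpc.coverage():.2f}")

obs = df.loc[df["EVID"] == 0, "DV"].to_numpy()
pred = population_predictions(df)
ppe = population_prediction_errors(obs, pred)
print(f"\n%PPE: median {ppe.median_ppe:+.1f}%, median |%PPE| "
      f"{ppe.median_abs_ppe:.1f}%, 75th pct |%PPE| {ppe.p75_abs_ppe:.1f}%")
print(f"external-validation rules pass: {ppe.passes}")
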