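"""Exposure-response time-to-relapse analysis on a synthetic trial.

Generates a censored relapse study from the exponential survival model
(threshold covariate: event-proximal Cmin below vs at-or-above 95 ng/mL),
then runs the full analysis chain: Kaplan-Meier description, log-rank test,
Cox fit with the proportional-hazards check, and the exponential AFT fit
with its survival-time ratio.
"""

import numpy as np

from aompk import (fit_cox_ph, fit_exponential_aft, generate_relapse_trial,
                   group_exposure, kaplan_meier, log_rank_test,
                   schoenfeld_ph_test)

records, truth = generate_relapse_trial(n=615, rng=np.random.default_rng(6))
quartile, high = group_exposure(records.CMIN.to_numpy())

print(f"subjects: {len(records)}, events: {records.EVENT.sum()}, "
      f"censored: {(1 - records.EVENT).sum()}")

km_low = kaplan_meier(records.TIME[high == 0], records.EVENT[high == 0])
km_high = kaplan_meier(records.TIME[high == 1], records.EVENT[high == 1])
t_mid = np.median(records.TIME)
print(f"KM survival at t={t_mid:.0f}:  low exposure {km_low.evaluate([t_mid])[0]:.3f}, "
      f"high exposure {km_high.evaluate([t_mid])[0]:.3f}")

chi2, p = log_rank_test(records.TIME, records.EVENT, high)
print(f"log-rank: chi2 = {chi2:.1f}, p = {p:.2e}")

cox = fit_cox_ph(records.TIME.to_numpy(), records.EVENT.to_numpy(),
                 high.astype(float))
r, p_ph = schoenfeld_ph_test(cox)
print(f"Cox log HR = {cox.coef:.3f} (SE {cox.se:.3f}); "
      f"PH check: Pearson r = {r:.3f}, p = {p_ph:.2f}")

aft = fit_exponential_aft(records.TIME, records.EVENT, high)
lo, hi = aft.survival_time_ratio_ci()
print(f"exponential AFT: intercept = {aft.intercept:.3f}, "
      f"beta = {aft.beta:.3f} (SE {aft.se_beta:.3f})")
print(f"survival-time ratio e^beta = {aft.survival_time_ratio:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f})")
print("\nA ratio of ~4.4 means subjects with Cmin >= 95 ng/mL are expected")
print("to remain relapse-free about 4.4 times longer than those below it.")
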