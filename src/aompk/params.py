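"""Published population parameters for the combined oral + once-monthly (AOM)
aripiprazole model.

All fixed-effect values, interindividual-variability (IIV) magnitudes and
residual-variability (RV) magnitudes of the final population model are
collected here as a single versioned constants table so that every module
draws on one source of truth.  Units follow the pharmacometric convention
used throughout the package: amounts in mg, volumes in L, times in h,
clearances in L/h, concentrations reported in ng/mL.
"""

from __future__ import annotations

from types import MappingProxyType

#: Version tag for the constants table (bump if values are ever revised).
CONSTANTS_VERSION = "final-model-v1"

#: Final population-model estimates (apparent, i.e. scaled by oral F).
TABLE = MappingProxyType(
    {
        # absorption
        "ka_oral": 0.540,        # 1/h, oral first-order absorption rate
        "r1": 9.33,              # mg/h, zero-order infusion of oral dose into its depot
        "ka_aom_ref": 0.000904,  # 1/h, depot absorption rate (female, BMI 28)
        "ka_aom_bmi_power": -0.975,
        "ka_aom_male_shift": 0.346,
        "f_aom": 1.48,           # AOM bioavailability relative to oral
        # disposition
        "cl_em": 3.71,           # L/h, clearance, CYP2D6 extensive metabolizer
        "cl_pm": 1.88,           # L/h, clearance, CYP2D6 poor metabolizer
        "cl_cyp2d6_inhibitor_shift": -0.511,
        "cl_cyp3a4_inhibitor_shift": -0.237,
        "vc": 93.4,              # L, central volume
        "q1": 0.591,             # L/h, first intercompartmental clearance
        "vp1": 118.0,            # L, first peripheral volume
        "q2": 28.8,              # L/h, second intercompartmental clearance
        "vp2": 134.0,            # L, second peripheral volume
        # interindividual variability, %CV (log-normal, diagonal)
        "iiv_cv_cl": 38.34,
        "iiv_cv_vc": 124.50,
        "iiv_cv_ka_oral": 65.88,
        "iiv_cv_ka_aom": 55.59,
        # proportional residual variability, %CV
        "rv_cv_phase1": 24.23,
        "rv_cv_phase3": 28.11,
    }
)

#: Reference BMI (kg/m^2) in the depot-absorption covariate equation.
BMI_REFERENCE = 28.0

#: Dosing-interval conventions: daily oral, every-4-weeks depot.
TAU_ORAL_H = 24.0
TAU_IM_H = 672.0

#: Exposure-response constants (exponential survival model of time to relapse).
ER_INTERCEPT = 6.256          # log survival time, reference (low-exposure) group
ER_BETA = 1.484               # log survival-time shift for Cmin >= threshold
ER_BETA_SE = 0.2177
ER_CMIN_THRESHOLD = 95.0      # ng/mL

#: Prevalence of the CYP2D6 extensive-metabolizer phenotype in the
#: general population, used as the mixture-model prior.
EM_PREVALENCE = 0.90
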