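# aompk

Population pharmacokinetics and exposure–response analysis for
**aripiprazole once-monthly (AOM)**, the long-acting intramuscular depot
formulation used for maintenance treatment of schizophrenia.

Nonadherence with daily oral antipsychotics is a major driver of relapse.
The depot formulation trades daily tablets for one injection every 28 days,
which raises concrete dosing questions: how should therapy be initiated so
concentrations reach an efficacious range quickly, how should doses be
adjusted for CYP2D6 poor metabolizers or patients on CYP2D6/CYP3A4
inhibitors, and how long can an injection be delayed before supplemental
oral dosing is needed?  This package implements, as a tested and reusable
pipeline, the published population-PK model and exposure–response survival
analysis that answer those questions — with a synthetic-data generator
standing in for the proprietary trial data, so every stage runs and is
testable out of the box.

## The model

**Population PK.**  A linear three-compartment mammillary disposition model
with two absorption paths, parameterized in apparent (oral-bioavailability
scaled) terms:

- oral dosing: a zero-order infusion of the dose into an oral depot at rate
  R1 = 9.33 mg/h followed by first-order transfer (Ka = 0.540 h⁻¹) — the
  "sigmoid" absorption that delays measurable concentrations;
- depot (IM) dosing: the bioavailable amount F2·dose (F2 = 1.48 relative to
  oral) enters an intramuscular depot and is absorbed first-order at

  Ka,AOM = 0.000904 · (BMI/28)^(−0.975) · (1 + 0.346·male)  h⁻¹,

  an absorption half-life of roughly 32 days for women and 24 days for men
  at BMI 28.  Because Ka,AOM is far below the slowest disposition
  eigenvalue, depot kinetics are *flip-flop*: the terminal decline after an
  injection reflects absorption, not elimination (terminal elimination
  half-life ≈ 7.5 days);
- clearance: CL/F = (3.71·EM + 1.88·PM) · (1 − 0.511·CYP2D6inh) ·
  (1 − 0.237·CYP3A4inh) L/h, with Vc/F = 93.4 L and fixed peripheral
  exchange (Q1 0.591, Vp1 118, Q2 28.8, Vp2 134);
- log-normal interindividual variability on CL, Vc, Ka and Ka,AOM
  (38–125 %CV) and proportional residual error (24–28 %CV by study phase).

Between input breakpoints the five-state system is advanced exactly with
matrix exponentials; periodic steady states are fixed points of the
one-interval affine propagation map.

**Therapeutic window.**  10 and 30 mg/day oral dosing are established as
safe and effective, so the window is defined by simulation of an
extensive-metabolizer virtual population: lower bound = median 10-mg
steady-state trough (≈ 94 ng/mL), upper bound = 75th percentile of the
30-mg steady-state peak (≈ 534 ng/mL).

**Exposure–response.**  Time to impending relapse is related to the
model-predicted trough proximate to the event (Cmin: 672 h after the last
monthly injection, or 24 h after the last oral dose during the first
injection period).  After Kaplan–Meier/Cox exploration showed
non-proportional hazards, the final model is an exponential
accelerated-failure-time fit with a threshold covariate x = 1{Cmin ≥ 95
ng/mL}: hazard λᵢ = exp(−(α + β·xᵢ)).  The fitted β = 1.484 gives a
survival-time ratio e^β = 4.41 (95% CI 2.89–6.75): patients at or above the
threshold are expected to remain relapse-free about 4.4 times longer.

## Worked example

```bash
python examples/exposure_response.py
```

```
subjects: 615, events: 82, censored: 533
KM survival at t=194:  low exposure 0.695, high exposure 0.924
log-rank: chi2 = 56.8, p = 4.92e-14
Cox log HR = -1.530 (SE 0.223); PH check: Pearson r = 0.032, p = 0.77
exponential AFT: intercept = 6.265, beta = 1.539 (SE 0.223)
survival-time ratio e^beta = 4.66 (95% CI 3.01-7.22)
```

The script simulates a censored relapse study (615 subjects, ~85 events,
25% below the exposure threshold — the shape of the original analysis
population) from the exponential model and refits it from scratch.  The
Kaplan–Meier estimates show the separation between exposure groups, the
log-rank test confirms it, and the AFT fit recovers the generating
parameters (α = 6.256, β = 1.484) within sampling error; the survival-time
ratio estimate of 4.66 sits inside its own confidence interval around the
published 4.41.

Other examples, one per capability: `therapeutic_window.py`,
`dose_initiation.py`, `missed_dose.py`, `model_evaluation.py` (VPC and
%PPE), `individual_estimation.py` (MAP etas, mixture phenotype
classification, event-proximal Cmin).

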