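# Methods

This note records the modeling and numerical choices behind `aompk`, in the
spirit of a pharmacometric analysis plan: what is assumed, what is
computed, and what the synthetic data do and do not establish.

## PK model structure and solution

The drug model is a five-state linear system over (oral depot, IM depot,
central, peripheral-1, peripheral-2), amounts in mg, volumes in L, times in
hours; central concentration is reported in ng/mL via the factor 1000 from
mg/L.  Oral "sigmoid" absorption is realized exactly as the published
parameterization states: the dose is infused into the oral depot at the
fixed rate R1 = 9.33 mg/h (duration = dose/R1) and transferred onward
first-order at 0.540 h⁻¹.  No separate lag parameter exists; the infusion
ramp *is* the lag.  IM doses deposit F2·dose into the depot instantaneously.
A dose of amount zero is a placebo administration: it adds nothing to the
system but anchors the event-proximal trough rule (below).

Consequences worth knowing:

- The system is linear in its *input function*.  Scaling IM amounts scales
  concentrations exactly; scaling an oral amount lengthens its infusion
  rather than amplifying it, so oral "linearity" is superposition of doses,
  not amplitude scaling.
- Between input breakpoints (dose starts, infusion ends) the state is
  propagated with the matrix exponential of the augmented constant system —
  exact up to floating point, no step-size error.  A stiff-ODE
  cross-integration agrees to 1e-6 relative (tested).
- Injection site is not a covariate (it was not selected in the source
  analysis); all IM doses share one Ka,AOM.

Steady state for dose q tau is computed as the fixed point of the
one-interval affine map x ↦ Mx + b (exact for linear systems); long
simulation to steady state is retained only as a cross-check.  The
interval AUC is accumulated exactly by augmenting the system with the
integral of the central amount.  Cmax is located on an intra-interval grid
(0.1 h oral, 1 h IM) and refined by local quadratic interpolation, bounding
the discretization error well below 0.1%.  The terminal half-life is
ln 2 / λ_z with λ_z the smallest-magnitude eigenvalue of the 3×3
disposition block; absorption states are excluded by construction.

## Variability conventions

Interindividual variability is diagonal log-normal on CL, Vc, oral Ka and
IM Ka.  Published magnitudes are %CV figures; two mappings to the
log-scale SD are supported because the reporting convention is not stated:
`omega_equals_cv` (ω = CV/100, the classic convention, the default) and
`lognormal_exact_cv` (ω² = ln(1+CV²), empirical CV matches exactly).
Medians are identical under either; means differ by under ~1% for CL.
Residual error is proportional and implemented log-normally
(conc·exp(ε)), which keeps simulated observations positive and makes the
MAP objective a sum of squared log residuals.

## Virtual populations

The simulation population is 60% male with log-normal BMI per sex.  The
BMI distribution of the source phase-3 population is not published in the
main text; the defaults (log-median 28 kg/m², log-SD 0.2 for both sexes)
center the distribution at the model's reference BMI, and all oral-dosing
targets are BMI-independent, so the window derivation does not depend on
this choice.  Metabolizer status is Bernoulli with 90% EM by default.  A
separate fixed-composition generator mirrors the 663-subject
model-development population: 621 EM / 42 PM, with 13 EM on CYP2D6
inhibitors and 25 EM on CYP3A4 inhibitors.

The therapeutic window is derived EM-only, with IIV and no residual error:
lower = median 10-mg q24h steady-state trough, upper = 75th percentile of
the 30-mg q24h steady-state peak, both per-subject exact steady-state
solves (n = 10,000 runs in ~15 s).  The window's lower bound (≈94 ng/mL)
and the exposure–response threshold (95 ng/mL) are numerically close but
distinct constants defined by different procedures; the code keeps them
separate.

Scenario summaries (initiation, CYP-based adjustment, missed doses) report
5th/50th/95th percentile concentration per day.  "Oral to steady state"
lead-in is 28 days of daily dosing — >93% of steady state and aligned with
the monthly cycle — configurable where exactness matters.  Missed-dose
schemes shift the named dose and all later doses; oral supplementation
runs 14 days from the reinitiation dose.  The depot-alone initiation arm
starts drug-naïve.

## Individual estimation

MAP (empirical-Bayes) etas minimize
Σ (log DV − log F(η))²/σ² + Σ η²/ω², consistent with the log-normal
residual model.  The optimizer is Nelder–Mead from η = 0 plus four jittered
restarts (tolerance 1e-8); with no observations the prior mode (η = 0) is
returned.  In sparse designs the estimates shrink toward zero, as they
must under a mean-zero prior; the tests verify both the shrinkage
direction and near-exact recovery under rich low-noise designs.  Random
effects that a design cannot inform (e.g. oral Ka in an IM-only study)
stay at the prior mode — recovery claims are only meaningful for
identifiable designs, so the recovery tests use a combined oral + IM
schedule.

Unknown CYP2D6 status is resolved by a two-component mixture: each
phenotype hypothesis is scored by its MAP-profiled likelihood
exp(−J_min/2) and combined with the 90% EM prevalence prior; the argmax is
assigned.  (Laplace-style integration over etas was considered and left
out: the assignment rule — "most probable status" — is unchanged by the
common Hessian factor in realistic designs.)  A consequence of the
published magnitudes deserves emphasis: the EM/PM clearance separation
(log 3.71/1.88 ≈ 0.68) is only ~1.8 SD of the clearance IIV, and a
clearance random effect can reproduce a PM profile under the EM
hypothesis, so the likelihood ratio in favor of PM is capped near 4.8
while the prior odds are 9:1 for EM.  A *typical* poor metabolizer is
therefore assigned EM; only clearly low-clearance subjects flip the
posterior.  This is a property of the model, not of the implementation,
and the test suite demonstrates correct assignment in regimes where the
phenotypes are actually separable (small IIV).

The event-proximal trough: events within 672 h of the first injection use
the prediction 24 h after the last oral dose; later events use 672 h after
the last administration (including placebo administrations, whose records
carry amount zero — predictions then continue the washout of earlier
active doses and can be arbitrarily small but stay positive).

## Exposure–response analysis

All survival estimators are implemented from first principles (lifelines
serves only as a cross-check oracle in tests): Kaplan–Meier with
events-first tie handling, the two-group log-rank test with hypergeometric
variance, a single-covariate Cox fit by Newton–Raphson on the Breslow
partial likelihood (monotone likelihoods are flagged and reported at a
bound), and the proportional-hazards check as the Pearson correlation of
raw Schoenfeld residuals with event time.  That correlation construction
— the one the source analysis describes — is mildly conservative: under
exact proportional hazards it rejects at roughly 2–3% for a nominal 5%
level (verified by simulation), which is acceptable for its role as a
gatekeeper toward the parametric model.

The exponential AFT with a binary threshold covariate has closed-form
MLEs (each group's rate = events / total follow-up); standard errors come
from the observed information, and the survival-time ratio is e^β with a
Wald interval.  The 95 ng/mL threshold is inclusive on the high side
(<95 vs ≥95).  The survival VPC redraws event times from the fitted model
under the observed censoring scheme (censored subjects keep their
follow-up as horizon; event subjects use the administrative maximum) and
reports median and 90% prediction bands of the replicated KM curves.

Synthetic relapse trials default to the shape of the analysis population:
615 subjects, 25% below the threshold, administrative censoring placed
where the expected event count is 85 (solved in closed form from the
exponential CDF), optional independent exponential dropout.  Event times
are generated in days; the source analysis does not state the time unit
of its intercept, and nothing here depends on it — recovery is
unit-invariant.  Synthetic Cmin values decorate the records uniformly
within each group's band and carry no information beyond group membership.

## Model evaluation machinery

%PPE = 100·(observed − population-predicted)/population-predicted, with
the external-validation rules |median %PPE| ≤ 10 and median |%PPE| < 40.
Note that data simulated from the model itself sit near the first rule's
boundary: with a 125 %CV log-normal on Vc the median observation falls
below the typical-subject prediction by around 10%, the same direction
and magnitude the original external validation reported (−6.8%).

The PK VPC re-simulates the dataset design (IIV + residual error) and
compares observed 5th/50th/95th percentiles to simulated confidence bands
within bins of time since previous dose (deciles by default, merged when
the design has few distinct sampling times; empty bins are dropped).
Observations below the quantification limit are not modeled — a
documented limitation, as the source handling of BQL records is unstated.

## Problem sizes and determinism

Default sizes follow the source analysis where it states them (10,000
virtual subjects for the window and scenario targets; 663-subject
development composition; 615-subject relapse trials; ≥200 replicates for
recovery).  Test-suite versions of stochastic calibration checks use
smaller sizes chosen so each check completes in seconds while keeping
Monte-Carlo error well inside the asserted bands; the acceptance script
uses the full sizes.  Every random draw flows through a
`numpy.random.Generator` passed explicitly, so all results are exactly
reproducible given a seed.

## Known limitations

- No metabolite (dehydro-aripiprazole) compartment, no nonlinear
  elimination, no inter-occasion variability, no random-effect
  correlations (inestimable in the source analysis).
- The 50/25-mg depot dose group is out of scope (the source model did not
  extrapolate to it), as are alternative survival families (Weibull,
  log-logistic, generalized gamma) and relapse-criteria scoring.
- Synthetic data reproduce the *statistical structure* the analysis
  assumes — log-normal IIV, proportional error, exponential relapse times
  with non-informative censoring.  Passing tests demonstrate correctness
  of the machinery and internal consistency of the published model, not
  the model's adequacy for any new clinical dataset.
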