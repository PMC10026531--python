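"""Synthetic study generation.

The original trial data are proprietary, so every pipeline stage is
exercised on synthetic studies that reproduce the statistical structure the
analysis assumes: rich serial sampling after a single depot injection
(phase-1-like), sparse trough-oriented sampling around monthly injections
(phase-3-like: predose plus single samples on days 7, 14 and 28 after
dosing), and censored relapse times drawn from the exponential
exposure-response model.  Every generator returns the dataset together with
its ground truth and is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import (CMT_CENTRAL, CMT_IM_DEPOT, CMT_ORAL_DEPOT, COLUMNS)
from .params import ER_BETA, ER_CMIN_THRESHOLD, ER_INTERCEPT
from .pk import Regimen, build_typical_parameters, simulate_concentrations
from .population import (OmegaSpec, PopulationSpec, SigmaSpec,
                         apply_residual_error, covariates_from_row,
                         generate_virtual_population,
                         sample_individual_parameters)
from .scenarios import aom_maintenance

__all__ = [
    "TrialDesign",
    "rich_phase1_design",
    "sparse_phase3_design",
    "generate_pk_trial",
    "generate_relapse_trial",
    "horizon_for_expected_events",
]


@dataclass(frozen=True)
class TrialDesign:
    """A PK sampling design: who is dosed how, and when samples are drawn."""

    label: str                      # {"rich_phase1", "sparse_phase3"}
    n: int
    regimen: Regimen
    sample_times_h: tuple[float, ...]
    followup_h: float
    phase: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.phase not in (1, 3):
            raise ValueError("phase must be 1 or 3")
        if any(t < 0 or t > self.followup_h for t in self.sample_times_h):
            raise ValueError("sampling schedule extends outside the follow-up window")


def rich_phase1_design(n: int = 20, dose_mg: float = 400.0) -> TrialDesign:
    """Single depot injection with dense serial sampling over ~3 months."""
    days = (1, 2, 4, 7, 10, 14, 21, 28, 35, 42, 56, 70, 84)
    return TrialDesign(
        label="rich_phase1",
        n=n,
        regimen=Regimen([d for d in aom_maintenance(dose_mg, 1).doses]),
        sample_times_h=tuple(24.0 * d for d in days),
        followup_h=24.0 * 90,
        phase=1,
    )


def sparse_phase3_design(n: int = 100, dose_mg: float = 400.0,
                         n_doses: int = 4) -> TrialDesign:
    """Monthly injections with trough-oriented sparse sampling: predose at
    every injection plus single samples on days 7, 14 and 28 after dosing."""
    times: set[float] = set()
    for k in range(n_doses):
        dose_day = 28.0 * k
        times.add(dose_day * 24.0)                   # predose trough
        for offset in (7.0, 14.0, 28.0):
            times.add((dose_day + offset) * 24.0)
    times.discard(0.0)  # nothing measurable before the first dose
    return TrialDesign(
        label="sparse_phase3",
        n=n,
        regimen=aom_maintenance(dose_mg, n_doses),
        sample_times_h=tuple(sorted(times)),
        followup_h=24.0 * 28.0 * (n_doses + 1),
        phase=3,
    )


def generate_pk_trial(design: TrialDesign, pop_spec: PopulationSpec | None = None,
                      omega: OmegaSpec | None = None,
                      sigma: SigmaSpec | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a complete PK study.

    Returns ``(dataset, truth)``: the NONMEM-style dataset (dose rows plus
    observation rows with residual error applied) and a per-subject ground
    truth table of the sampled individual parameters, for recovery tests.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    omega = OmegaSpec() if omega is None else omega
    sigma = SigmaSpec() if sigma is None else sigma
    pop_spec = PopulationSpec(n=design.n) if pop_spec is None else pop_spec
    if pop_spec.n != design.n:
        raise ValueError("population spec size must match the design size")
    pop = generate_virtual_population(pop_spec, rng)
    rows = []
    truth_rows = []
    times = np.asarray(sorted(design.sample_times_h), dtype=float)
    for row in pop.itertuples(index=False):
        row_d = row._asdict()
        cov = covariates_from_row(row_d)
        typical = build_typical_parameters(cov)
        params = sample_individual_parameters(typical, omega, rng)
        pred = simulate_concentrations(params, design.regimen, times).conc
        dv = apply_residual_error(pred, design.phase, sigma, rng)
        base = {
            "ID": row_d["ID"], "SEX": row_d["SEX"], "BMI": row_d["BMI"],
            "PM": row_d["PM"], "CYP2D6INH": row_d["CYP2D6INH"],
            "CYP3A4INH": row_d["CYP3A4INH"], "PHASE": design.phase,
        }
        for d in design.regimen.doses:
            rows.append({**base, "TIME": d.time, "AMT": d.amount,
                         "RATE": params.r1 if d.route == "oral" else 0.0,
                         "CMT": CMT_ORAL_DEPOT if d.route == "oral" else CMT_IM_DEPOT,
                         "EVID": 1, "MDV": 1, "DV": 0.0})
        for t, c in zip(times, dv):
            rows.append({**base, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                         "CMT": CMT_CENTRAL, "EVID": 0, "MDV": 0, "DV": c})
        truth_rows.append({
            "ID": row_d["ID"], "CL": params.cl, "VC": params.vc,
            "KA_ORAL": params.ka_oral, "KA_AOM": params.ka_aom,
            "CL_TYPICAL": typical.cl, "VC_TYPICAL": typical.vc,
            "KA_ORAL_TYPICAL": typical.ka_oral, "KA_AOM_TYPICAL": typical.ka_aom,
        })
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        ascending=[True, True, False])
    df = df.reset_index(drop=True)[COLUMNS]
    return df, pd.DataFrame(truth_rows)


def horizon_for_expected_events(n: int, low_fraction: float,
                                intercept: float, beta: float,
                                target_events: float,
                                dropout_hazard: float = 0.0) -> float:
    """Administrative censoring horizon (same time unit as exp(intercept))
    at which the expected number of observed events equals the target."""
    lam_low = np.exp(-intercept)
    lam_high = np.exp(-(intercept + beta))
    n_low = n * low_fraction
    n_high = n - n_low

    def expected(h):
        total = 0.0
        for lam, count in ((lam_low, n_low), (lam_high, n_high)):
            rate = lam + dropout_hazard
            total += count * (lam / rate) * (1.0 - np.exp(-rate * h))
        return total - target_events

    upper = 50.0 / min(lam_low, lam_high)
    if expected(upper) < 0:
        raise ValueError("target events unreachable under this design")
    return float(brentq(expected, 1e-9, upper))


def generate_relapse_trial(n: int = 615, intercept: float = ER_INTERCEPT,
                           beta: float = ER_BETA,
                           low_group_fraction: float = 0.25,
                           censor_horizon: float | None = None,
                           dropout_hazard: float = 0.0,
                           target_events: float = 85.0,
                           threshold: float = ER_CMIN_THRESHOLD,
                           rng: np.random.Generator | None = None
                           ) -> tuple[pd.DataFrame, dict]:
    """Simulate a censored relapse study under the exponential AFT model.

    Group membership (below/at-or-above the Cmin threshold) is assigned to
    exact counts; synthetic Cmin values are drawn uniformly within each
    group's band purely as record decoration.  Event times are exponential
    with log mean survival ``intercept + beta * high``; independent
    exponential dropout and administrative censoring at the horizon are
    applied.  When no horizon is given it is placed where the expected
    number of events matches ``target_events``.

    Returns ``(records, truth)`` where records has columns
    ID, TIME, EVENT, CMIN, GROUP and truth carries the generating values.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0.0 < low_group_fraction < 1.0:
        raise ValueError("low_group_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(0) if rng is None else rng
    if censor_horizon is None:
        censor_horizon = horizon_for_expected_events(
            n, low_group_fraction, intercept, beta, target_events, dropout_hazard)
    n_low = int(round(n * low_group_fraction))
    n_low = min(max(n_low, 1), n - 1)
    high = np.ones(n, dtype=int)
    high[:n_low] = 0
    rng.shuffle(high)
    cmin = np.where(high == 1,
                    rng.uniform(threshold, 4.0 * threshold, size=n),
                    rng.uniform(0.5, threshold, size=n))
    mean_t = np.exp(intercept + beta * high)
    t_event = rng.exponential(mean_t)
    t_obs = np.minimum(t_event, censor_horizon)
    event = (t_event <= censor_horizon).astype(int)
    if dropout_hazard > 0:
        t_drop = rng.exponential(1.0 / dropout_hazard, size=n)
        event = np.where(t_drop < t_obs, 0, event)
        t_obs = np.minimum(t_obs, t_drop)
    records = pd.DataFrame({
        "ID": np.arange(1, n + 1),
        "TIME": t_obs,
        "EVENT": event,
        "CMIN": cmin,
        "GROUP": high,
    })
    truth = {"intercept": intercept, "beta": beta,
             "censor_horizon": float(censor_horizon),
             "dropout_hazard": dropout_hazard,
             "n_low": int(n_low), "threshold": threshold}
    return records, truth
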