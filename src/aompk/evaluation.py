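"""Model-evaluation machinery: the simulation-based visual predictive check
(VPC) for the PK model and the percent population prediction error (%PPE)
statistics used for external validation.

%PPE for one record is 100 * (observed - population predicted) / population
predicted.  A dose group is considered adequately described when the median
%PPE lies within +/-10% and the median |%PPE| is below 40%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import dataset_to_subjects
from .pk import build_typical_parameters, simulate_concentrations
from .population import (OmegaSpec, SigmaSpec, apply_residual_error,
                         sample_individual_parameters)

__all__ = [
    "PPESummary",
    "VPCResult",
    "population_prediction_errors",
    "population_predictions",
    "pk_vpc",
]

PERCENTILES = (5.0, 50.0, 95.0)


@dataclass(frozen=True)
class PPESummary:
    """Summary of per-record population prediction errors."""

    ppe: np.ndarray
    median_ppe: float
    median_abs_ppe: float
    p75_abs_ppe: float

    @property
    def passes_median_rule(self) -> bool:
        return abs(self.median_ppe) <= 10.0

    @property
    def passes_abs_rule(self) -> bool:
        return self.median_abs_ppe < 40.0

    @property
    def passes(self) -> bool:
        return self.passes_median_rule and self.passes_abs_rule


@dataclass(frozen=True)
class VPCResult:
    """Binned observed percentiles with simulated confidence bands."""

    table: pd.DataFrame
    n_reps: int

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed percentile
        falls inside the simulated confidence band."""
        inside = 0
        total = 0
        for p in PERCENTILES:
            obs = self.table[f"obs_p{p:g}"]
            lo = self.table[f"sim_p{p:g}_lo"]
            hi = self.table[f"sim_p{p:g}_hi"]
            inside += int(((obs >= lo) & (obs <= hi)).sum())
            total += len(self.table)
        return inside / total


def population_prediction_errors(observed, predicted) -> PPESummary:
    """Per-record %PPE plus the external-validation summary statistics."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal shapes")
    if obs.size == 0:
        raise ValueError("at least one record is required")
    if np.any(pred <= 0):
        raise ValueError("population predictions must be positive")
    ppe = 100.0 * (obs - pred) / pred
    return PPESummary(
        ppe=ppe,
        median_ppe=float(np.median(ppe)),
        median_abs_ppe=float(np.median(np.abs(ppe))),
        p75_abs_ppe=float(np.percentile(np.abs(ppe), 75)),
    )


def population_predictions(df: pd.DataFrame) -> np.ndarray:
    """Typical-subject (population) predictions at every observation row,
    in dataset row order of the observation records."""
    preds = []
    for rec in dataset_to_subjects(df):
        params = build_typical_parameters(rec.covariates)
        obs = rec.observations
        order = np.argsort(obs.times, kind="stable")
        p = np.empty(len(obs))
        p[order] = simulate_concentrations(params, rec.regimen,
                                           obs.times[order]).conc
        preds.append(p)
    return np.concatenate(preds) if preds else np.array([])


def _time_since_previous_dose(rec) -> np.ndarray:
    dose_times = np.array([d.time for d in rec.regimen.doses])
    out = np.empty(len(rec.observations))
    for i, t in enumerate(rec.observations.times):
        before = dose_times[dose_times <= t]
        out[i] = t - before.max() if before.size else np.nan
    return out


def pk_vpc(df: pd.DataFrame, n_reps: int = 1000,
           omega: OmegaSpec | None = None, sigma: SigmaSpec | None = None,
           rng: np.random.Generator | None = None,
           n_bins: int = 10, ci: float = 0.95) -> VPCResult:
    """Simulation-based VPC of a PK dataset against the population model.

    The study design (dosing, sampling times, covariates) is re-simulated
    ``n_reps`` times with interindividual variability and residual error;
    observed and simulated 5th/50th/95th percentiles are compared within
    bins of time since the previous dose (up to deciles, merged when the
    dataset has few distinct sampling times).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    omega = OmegaSpec() if omega is None else omega
    sigma = SigmaSpec() if sigma is None else sigma
    subjects = dataset_to_subjects(df)
    if not any(len(s.observations) for s in subjects):
        raise ValueError("dataset contains no observations")
    obs_dv = np.concatenate([s.observations.dv for s in subjects])
    tspd = np.concatenate([_time_since_previous_dose(s) for s in subjects])
    phases = np.concatenate([s.observations.phase for s in subjects])
    if np.any(np.isnan(tspd)):
        raise ValueError("observations before any dose are not supported")
    edges = np.unique(np.quantile(tspd, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        edges = np.array([tspd.min() - 0.5, tspd.max() + 0.5])
    bin_idx = np.clip(np.searchsorted(edges, tspd, side="right") - 1,
                      0, edges.size - 2)

    def binned_percentiles(values: np.ndarray) -> np.ndarray:
        out = np.empty((edges.size - 1, len(PERCENTILES)))
        for b in range(edges.size - 1):
            sel = bin_idx == b
            out[b] = (np.percentile(values[sel], PERCENTILES)
                      if sel.any() else np.nan)
        return out

    observed = binned_percentiles(obs_dv)
    sims = np.empty((n_reps, edges.size - 1, len(PERCENTILES)))
    for r in range(n_reps):
        sim_dv = []
        for s in subjects:
            params = sample_individual_parameters(
                build_typical_parameters(s.covariates), omega, rng)
            obs = s.observations
            order = np.argsort(obs.times, kind="stable")
            pred = np.empty(len(obs))
            pred[order] = simulate_concentrations(params, s.regimen,
                                                  obs.times[order]).conc
            sim_dv.append(pred)
        sim_dv = np.concatenate(sim_dv)
        noisy = np.empty_like(sim_dv)
        for ph in np.unique(phases):
            sel = phases == ph
            noisy[sel] = apply_residual_error(sim_dv[sel], int(ph), sigma, rng)
        sims[r] = binned_percentiles(noisy)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    occupied = np.array([np.any(bin_idx == b) for b in range(edges.size - 1)])
    rows = {}
    mids = 0.5 * (edges[:-1] + edges[1:])
    rows["t_mid"] = mids
    for j, p in enumerate(PERCENTILES):
        rows[f"obs_p{p:g}"] = observed[:, j]
        rows[f"sim_p{p:g}_med"] = np.median(sims[:, :, j], axis=0)
        rows[f"sim_p{p:g}_lo"] = np.quantile(sims[:, :, j], lo_q, axis=0)
        rows[f"sim_p{p:g}_hi"] = np.quantile(sims[:, :, j], hi_q, axis=0)
    table = pd.DataFrame(rows)[occupied].reset_index(drop=True)
    return VPCResult(table=table, n_reps=n_reps)
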