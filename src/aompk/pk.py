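"""Deterministic core of the aripiprazole oral + depot population PK model.

The drug model is a linear five-state system: an oral depot filled by a
zero-order infusion (the "sigmoid" oral absorption: the dose is infused into
the depot at a fixed rate R1 and transferred onward first-order), an
intramuscular depot receiving the bioavailable fraction of each once-monthly
(AOM) injection instantaneously and draining first-order at a slow,
covariate-dependent rate, and a three-compartment mammillary disposition
block (central + two peripheral).  Because the depot rate constant is far
smaller than the slowest disposition eigenvalue, depot kinetics are
flip-flop: the terminal decline after an injection is governed by
absorption, not elimination.

All solutions are exact for the linear system: between input breakpoints the
state is advanced with the matrix exponential of the (augmented) constant
system, and periodic steady states are obtained as the fixed point of the
one-interval affine propagation map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

from .params import BMI_REFERENCE, TABLE

__all__ = [
    "SubjectCovariates",
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "ExposureMetrics",
    "clearance_from_covariates",
    "ka_aom_from_covariates",
    "build_typical_parameters",
    "disposition_rate_constants",
    "disposition_matrix",
    "system_matrix",
    "terminal_half_life",
    "absorption_half_life",
    "simulate_concentrations",
    "simulate_amounts",
    "steady_state_exposures",
]

# state ordering of the linear system
ORAL_DEPOT, IM_DEPOT, CENTRAL, PERIPH1, PERIPH2 = range(5)
N_STATES = 5

SEXES = ("male", "female")
METABOLIZERS = ("EM", "PM", "unknown")
ROUTES = ("oral", "im")


class UnresolvedMetabolizerError(ValueError):
    """Raised when a covariate equation needs a resolved CYP2D6 phenotype."""


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates entering the final model's parameter equations.

    ``metabolizer`` may be ``"unknown"`` for raw study subjects; it must be
    resolved (e.g. by :func:`aompk.bayes.classify_metabolizer_mixture`)
    before typical parameters can be built.
    """

    sex: str
    bmi: float
    metabolizer: str = "EM"
    on_cyp2d6_inhibitor: bool = False
    on_cyp3a4_inhibitor: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.metabolizer not in METABOLIZERS:
            raise ValueError(
                f"metabolizer must be one of {METABOLIZERS}, got {self.metabolizer!r}"
            )
        if not (10.0 < float(self.bmi) < 80.0):
            raise ValueError(f"bmi must lie in (10, 80) kg/m^2, got {self.bmi}")


@dataclass(frozen=True)
class PKParameters:
    """Individual parameter vector of the five-state model (apparent scale)."""

    cl: float        # L/h
    vc: float        # L
    q1: float        # L/h
    vp1: float       # L
    q2: float        # L/h
    vp2: float       # L
    ka_oral: float   # 1/h
    ka_aom: float    # 1/h
    f_aom: float     # relative bioavailability of the depot dose
    r1: float        # mg/h, zero-order oral input rate

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q1", "vp1", "q2", "vp2", "ka_oral", "ka_aom",
                     "f_aom", "r1"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {value}")
        for name in ("cl", "vc", "ka_oral", "ka_aom", "f_aom", "r1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def with_etas(self, eta_cl: float = 0.0, eta_vc: float = 0.0,
                  eta_ka_oral: float = 0.0, eta_ka_aom: float = 0.0) -> "PKParameters":
        """Return a copy with log-normal random effects applied."""
        return replace(
            self,
            cl=self.cl * float(np.exp(eta_cl)),
            vc=self.vc * float(np.exp(eta_vc)),
            ka_oral=self.ka_oral * float(np.exp(eta_ka_oral)),
            ka_aom=self.ka_aom * float(np.exp(eta_ka_aom)),
        )


@dataclass(frozen=True)
class DoseEvent:
    """A single administration.

    Oral doses enter the oral depot as a zero-order infusion of duration
    ``amount / r1``; IM doses deposit ``amount * f_aom`` into the depot
    instantaneously.  A zero amount records a placebo administration: it
    adds no drug but anchors the event-proximal trough rule for subjects
    randomized to placebo.
    """

    time: float    # h
    amount: float  # mg
    route: str

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")
        if self.amount < 0:
            raise ValueError("dose amount must be nonnegative")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of doses plus the interval conventions."""

    doses: tuple[DoseEvent, ...]
    tau_oral: float = 24.0
    tau_im: float = 672.0

    def __init__(self, doses: Iterable[DoseEvent], tau_oral: float = 24.0,
                 tau_im: float = 672.0):
        doses = tuple(sorted(doses, key=lambda d: d.time))
        if tau_oral <= 0 or tau_im <= 0:
            raise ValueError("dosing intervals must be positive")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "tau_oral", float(tau_oral))
        object.__setattr__(self, "tau_im", float(tau_im))

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment model predictions (no residual error), ng/mL."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.conc):
            raise ValueError("times and conc must have equal length")


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summaries over one dosing interval."""

    cmin_ss: float    # ng/mL, pre-dose trough
    cmax_ss: float    # ng/mL
    cavg_ss: float    # ng/mL
    auc_tau_ss: float  # mg*h/L
    tau: float        # h


# ---------------------------------------------------------------------------
# covariate equations and parameter assembly
# ---------------------------------------------------------------------------

def clearance_from_covariates(cov: SubjectCovariates) -> float:
    """Typical apparent clearance (L/h) under the final covariate model.

    CL/F = (3.71*EM + 1.88*PM) * (1 - 0.511*CYP2D6inh) * (1 - 0.237*CYP3A4inh)
    """
    if cov.metabolizer == "unknown":
        raise UnresolvedMetabolizerError(
            "CYP2D6 metabolizer status is 'unknown'; resolve it first with "
            "aompk.bayes.classify_metabolizer_mixture"
        )
    base = TABLE["cl_em"] if cov.metabolizer == "EM" else TABLE["cl_pm"]
    cl = base
    if cov.on_cyp2d6_inhibitor:
        cl *= 1.0 + TABLE["cl_cyp2d6_inhibitor_shift"]
    if cov.on_cyp3a4_inhibitor:
        cl *= 1.0 + TABLE["cl_cyp3a4_inhibitor_shift"]
    return cl


def ka_aom_from_covariates(cov: SubjectCovariates) -> float:
    """Typical depot absorption rate constant (1/h).

    ka = 0.000904 * (BMI/28)^-0.975 * (1 + 0.346*male)
    """
    if cov.bmi <= 0:
        raise ValueError("bmi must be positive")
    ka = TABLE["ka_aom_ref"] * (cov.bmi / BMI_REFERENCE) ** TABLE["ka_aom_bmi_power"]
    if cov.sex == "male":
        ka *= 1.0 + TABLE["ka_aom_male_shift"]
    return ka


def build_typical_parameters(cov: SubjectCovariates) -> PKParameters:
    """Assemble the full typical parameter vector for a subject."""
    return PKParameters(
        cl=clearance_from_covariates(cov),
        vc=TABLE["vc"],
        q1=TABLE["q1"],
        vp1=TABLE["vp1"],
        q2=TABLE["q2"],
        vp2=TABLE["vp2"],
        ka_oral=TABLE["ka_oral"],
        ka_aom=ka_aom_from_covariates(cov),
        f_aom=TABLE["f_aom"],
        r1=TABLE["r1"],
    )


# ---------------------------------------------------------------------------
# linear-system plumbing
# ---------------------------------------------------------------------------

def disposition_rate_constants(params: PKParameters) -> dict[str, float]:
    """Micro rate constants (1/h) of the mammillary disposition block."""
    return {
        "k10": params.cl / params.vc,
        "k12": params.q1 / params.vc,
        "k21": params.q1 / params.vp1 if params.vp1 > 0 else 0.0,
        "k13": params.q2 / params.vc,
        "k31": params.q2 / params.vp2 if params.vp2 > 0 else 0.0,
    }


def disposition_matrix(params: PKParameters) -> np.ndarray:
    """3x3 rate matrix of the disposition block (central, periph1, periph2)."""
    k = disposition_rate_constants(params)
    return np.array(
        [
            [-(k["k10"] + k["k12"] + k["k13"]), k["k21"], k["k31"]],
            [k["k12"], -k["k21"], 0.0],
            [k["k13"], 0.0, -k["k31"]],
        ]
    )


def system_matrix(params: PKParameters) -> np.ndarray:
    """5x5 rate matrix over (oral depot, im depot, central, periph1, periph2)."""
    K = np.zeros((N_STATES, N_STATES))
    K[ORAL_DEPOT, ORAL_DEPOT] = -params.ka_oral
    K[IM_DEPOT, IM_DEPOT] = -params.ka_aom
    K[CENTRAL, ORAL_DEPOT] = params.ka_oral
    K[CENTRAL, IM_DEPOT] = params.ka_aom
    K[CENTRAL:, CENTRAL:] = disposition_matrix(params)
    return K


def terminal_half_life(params: PKParameters) -> float:
    """Terminal elimination half-life (h): ln2 over the smallest-magnitude
    eigenvalue of the disposition block (absorption states excluded)."""
    eigvals = np.linalg.eigvals(disposition_matrix(params))
    real = eigvals.real
    if np.any(np.abs(eigvals.imag) > 1e-9 * np.max(np.abs(real))):
        raise ArithmeticError(f"complex disposition eigenvalues: {eigvals}")
    lam_z = np.min(np.abs(real[real < 0]))
    return float(np.log(2) / lam_z)


def absorption_half_life(params: PKParameters, route: str) -> float:
    """Absorption half-life (h) for the given route, ln2/ka."""
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}")
    ka = params.ka_oral if route == "oral" else params.ka_aom
    return float(np.log(2) / ka)


def _segment_step(K: np.ndarray, rate: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact affine update over dt under constant oral-depot infusion `rate`.

    Returns (M, b) with x(t+dt) = M @ x(t) + b, computed from the matrix
    exponential of the augmented constant system.
    """
    n = K.shape[0]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = K * dt
    if rate != 0.0:
        A[ORAL_DEPOT, n] = rate * dt
    E = expm(A)
    return E[:n, :n], E[:n, n]


def _dose_events(params: PKParameters, regimen: Regimen):
    """Break a regimen into infusion-rate deltas and instantaneous boluses."""
    rate_delta: dict[float, float] = {}
    bolus: dict[float, float] = {}
    for d in regimen.doses:
        if d.amount == 0.0:  # placebo administration: no input
            continue
        if d.route == "oral":
            stop = d.time + d.amount / params.r1
            rate_delta[d.time] = rate_delta.get(d.time, 0.0) + params.r1
            rate_delta[stop] = rate_delta.get(stop, 0.0) - params.r1
        else:
            bolus[d.time] = bolus.get(d.time, 0.0) + d.amount * params.f_aom
    return rate_delta, bolus


def simulate_amounts(params: PKParameters, regimen: Regimen,
                     times: Sequence[float]) -> np.ndarray:
    """Exact state trajectory; rows are requested times, columns the 5 states.

    Overlapping oral infusions superpose (rates add).  Times must be
    ascending and nonnegative.
    """
    t_out = np.asarray(times, dtype=float)
    if t_out.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t_out.size and (np.any(np.diff(t_out) < 0) or t_out[0] < 0):
        raise ValueError("times must be ascending and nonnegative")
    out = np.zeros((t_out.size, N_STATES))
    if t_out.size == 0 or len(regimen) == 0:
        return out
    K = system_matrix(params)
    rate_delta, bolus = _dose_events(params, regimen)
    horizon = t_out[-1]
    event_times = sorted(
        {t for t in rate_delta if t <= horizon} | {t for t in bolus if t <= horizon}
    )
    grid = np.union1d(t_out, np.asarray(event_times))
    x = np.zeros(N_STATES)
    t = 0.0
    rate = 0.0
    cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}
    for tp in grid:
        dt = tp - t
        if dt > 0:
            key = (dt, rate)
            if key not in cache:
                cache[key] = _segment_step(K, rate, dt)
            M, b = cache[key]
            x = M @ x + b
        t = tp
        if tp in bolus:
            x = x.copy()
            x[IM_DEPOT] += bolus[tp]
        if tp in rate_delta:
            rate += rate_delta[tp]
        lo, hi = np.searchsorted(t_out, tp, side="left"), np.searchsorted(t_out, tp, side="right")
        if hi > lo:
            out[lo:hi] = x
    return out


def simulate_concentrations(params: PKParameters, regimen: Regimen,
                            times: Sequence[float]) -> ConcentrationProfile:
    """Central-compartment concentration (ng/mL) at the requested times."""
    amounts = simulate_amounts(params, regimen, times)
    conc = 1000.0 * amounts[:, CENTRAL] / params.vc
    return ConcentrationProfile(times=np.asarray(times, dtype=float), conc=conc)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def _interval_segments(params: PKParameters, dose: float, route: str,
                       tau: float) -> tuple[list[tuple[float, float]], np.ndarray]:
    """One dosing interval as (duration, infusion rate) segments plus the
    instantaneous bolus applied at the interval start."""
    bolus = np.zeros(N_STATES)
    if route == "oral":
        duration = dose / params.r1
        if duration >= tau:
            raise ValueError("oral infusion duration exceeds the dosing interval")
        segments = [(duration, params.r1), (tau - duration, 0.0)]
    elif route == "im":
        bolus[IM_DEPOT] = dose * params.f_aom
        segments = [(tau, 0.0)]
    else:
        raise ValueError(f"route must be one of {ROUTES}")
    return segments, bolus


def steady_state_exposures(params: PKParameters, dose: float, route: str,
                           tau: float, cmax_grid_h: float | None = None) -> ExposureMetrics:
    """Periodic steady-state exposure metrics for dose q`tau`h by `route`.

    The pre-dose steady state is the fixed point of the one-interval affine
    propagation map (exact for the linear system); Cmax is located on a dense
    intra-interval grid (0.1 h oral, 1 h IM by default) and refined by local
    quadratic interpolation; the AUC over the interval is accumulated exactly
    by augmenting the system with the integral of the central amount.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dose <= 0:
        raise ValueError("dose must be positive")
    K = system_matrix(params)
    segments, bolus = _interval_segments(params, dose, route, tau)
    M = np.eye(N_STATES)
    b = np.zeros(N_STATES)
    for dt, rate in segments:
        Mi, bi = _segment_step(K, rate, dt)
        M = Mi @ M
        b = Mi @ b + bi
    try:
        x_pre = np.linalg.solve(np.eye(N_STATES) - M, M @ bolus + b)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise ArithmeticError("singular one-interval propagation map") from err
    cmin = 1000.0 * x_pre[CENTRAL] / params.vc

    # AUC via the augmented integrator state over one interval
    K6 = np.zeros((N_STATES + 1, N_STATES + 1))
    K6[:N_STATES, :N_STATES] = K
    K6[N_STATES, CENTRAL] = 1.0
    x6 = np.append(x_pre + bolus, 0.0)
    for dt, rate in segments:
        M6, b6 = _segment_step(K6, rate, dt)
        x6 = M6 @ x6 + b6
    auc_tau = x6[N_STATES] / params.vc  # mg*h/L
    cavg = auc_tau * 1000.0 / tau

    # Cmax on a dense grid with quadratic refinement
    step = cmax_grid_h if cmax_grid_h is not None else (0.1 if route == "oral" else 1.0)
    concs = [1000.0 * (x_pre + bolus)[CENTRAL] / params.vc]
    x = x_pre + bolus
    step_cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}
    for dt_seg, rate in segments:
        n_full, rem = int(dt_seg // step), dt_seg % step
        key = (step, rate)
        if key not in step_cache:
            step_cache[key] = _segment_step(K, rate, step)
        Ms, bs = step_cache[key]
        for _ in range(n_full):
            x = Ms @ x + bs
            concs.append(1000.0 * x[CENTRAL] / params.vc)
        if rem > 1e-12:
            Mr, br = _segment_step(K, rate, rem)
            x = Mr @ x + br
            concs.append(1000.0 * x[CENTRAL] / params.vc)
    concs = np.asarray(concs)
    i = int(np.argmax(concs))
    cmax = float(concs[i])
    if 0 < i < len(concs) - 1:
        y0, y1, y2 = concs[i - 1], concs[i], concs[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # strict local maximum: refine on the fitted parabola
            cmax = float(y1 - (y0 - y2) ** 2 / (8 * denom))
    cmax = max(cmax, cmin)
    return ExposureMetrics(cmin_ss=float(cmin), cmax_ss=cmax, cavg_ss=float(cavg),
                           auc_tau_ss=float(auc_tau), tau=float(tau))
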