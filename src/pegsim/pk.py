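"""One-compartment population PK model with first-order subcutaneous absorption.

The structural model is a linear one-compartment disposition with a depot
absorption compartment (the parsimonious default for a 40 kDa PEG-rhGH
conjugate; swappable if richer data ever support more compartments).
Clearance and volume scale allometrically with body weight; between-subject
variability is lognormal. All solutions are analytic: a single dose follows
the Bateman function, multiple doses are handled by exact piecewise
propagation of the depot/central amounts (equivalent to superposition for
linear PK), and interval AUCs are closed-form integrals of the same states.

Units: hours, mg, L; concentrations are mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PkParams",
    "IndividualPk",
    "DoseEvent",
    "ConcProfile",
    "individual_params",
    "conc_single_dose",
    "simulate_pk",
    "auc_interval",
    "cumulative_auc",
    "steady_state_conc",
    "steady_state_auc_tau",
]

# relative |ka - ke| below which the Bateman form switches to its ka -> ke limit
_KA_KE_TOL = 1e-10


@dataclass(frozen=True)
class PkParams:
    """Population PK parameters at the reference body weight.

    ``cl_pop``/``v_pop`` are clearance (L/h) and central volume (L) for a
    ``wt_ref`` kg subject; ``ka_pop`` is the first-order absorption rate
    (1/h); ``f_bio`` the absolute bioavailability. ``exp_cl``/``exp_v`` are
    allometric exponents. ``omega_*`` are between-subject SDs on the log
    scale and ``sigma_prop``/``sigma_add`` the proportional and additive
    residual-error SDs used by the observation generators and by estimation.
    """

    cl_pop: float
    v_pop: float
    ka_pop: float
    f_bio: float = 1.0
    wt_ref: float = 25.0
    exp_cl: float = 0.75
    exp_v: float = 1.0
    omega_cl: float = 0.0
    omega_v: float = 0.0
    omega_ka: float = 0.0
    sigma_prop: float = 0.0
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl_pop", "v_pop", "ka_pop", "f_bio", "wt_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PkParams.{name} must be > 0")
        for name in ("omega_cl", "omega_v", "omega_ka", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"PkParams.{name} must be >= 0")
        for name in ("exp_cl", "exp_v"):
            if not 0.0 <= getattr(self, name) <= 2.0:
                raise ValueError(f"PkParams.{name} must be in [0, 2]")


@dataclass(frozen=True)
class IndividualPk:
    """Individualized PK parameters for one subject."""

    cl: float
    v: float
    ka: float
    f: float = 1.0

    @property
    def ke(self) -> float:
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    """A subcutaneous depot dose: ``time`` in hours since first dose, ``amount`` in mg."""

    time: float
    amount: float
    route: str = "depot"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.route != "depot":
            raise ValueError(f"unsupported route {self.route!r}; only 'depot' is modeled")


@dataclass
class ConcProfile:
    """Concentration-time profile on a strictly increasing grid."""

    times: np.ndarray
    conc: np.ndarray
    subject_id: str | int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.conc.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < -1e-12):
            raise ValueError("concentrations must be non-negative")


def individual_params(
    pop: PkParams, weight: float, etas=(0.0, 0.0, 0.0)
) -> IndividualPk:
    """Individual CL/V/ka from population values, body weight and etas.

    ``etas`` is the (eta_cl, eta_v, eta_ka) vector of subject-level random
    effects on the log scale: CL_i = CL_pop * (WT/WT_ref)^exp_cl * exp(eta_cl),
    and analogously for V and ka (ka is not weight-scaled).
    """
    if not weight > 0:
        raise ValueError("weight must be > 0")
    etas = np.asarray(etas, dtype=float)
    if etas.shape != (3,):
        raise ValueError("etas must be a length-3 vector (cl, v, ka)")
    if not np.all(np.isfinite(etas)):
        raise ValueError("etas must be finite")
    fw = weight / pop.wt_ref
    cl = pop.cl_pop * fw**pop.exp_cl * math.exp(etas[0])
    v = pop.v_pop * fw**pop.exp_v * math.exp(etas[1])
    ka = pop.ka_pop * math.exp(etas[2])
    return IndividualPk(cl=cl, v=v, ka=ka, f=pop.f_bio)


def conc_single_dose(p: IndividualPk, dose: float, t) -> np.ndarray | float:
    """Bateman concentration after a single depot dose at t=0.

    C(t) = F*D*ka / (V*(ka-ke)) * (exp(-ke t) - exp(-ka t)); when ka == ke
    the limiting form F*D*ka*t*exp(-ka t)/V is used.  t < 0 maps to 0.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    tt = np.maximum(t_arr, 0.0)
    ke = p.ke
    if abs(p.ka - ke) <= _KA_KE_TOL * p.ka:
        c = p.f * dose * p.ka * tt * np.exp(-p.ka * tt) / p.v
    else:
        coef = p.f * dose * p.ka / (p.v * (p.ka - ke))
        c = coef * (np.exp(-ke * tt) - np.exp(-p.ka * tt))
    c = np.where(t_arr < 0, 0.0, c)
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def _sorted_events(doses) -> list[tuple[float, float]]:
    """Merge dose events into a sorted (time, bioavailable-amount-multiplier) list."""
    ev: dict[float, float] = {}
    for d in doses:
        ev[d.time] = ev.get(d.time, 0.0) + d.amount
    return sorted(ev.items())


def _segment_conc(p: IndividualPk, a0: float, x0: float, tau: np.ndarray) -> np.ndarray:
    """Central concentration at offsets ``tau`` given depot/central amounts at tau=0."""
    ke = p.ke
    eka = np.exp(-p.ka * tau)
    eke = np.exp(-ke * tau)
    if abs(p.ka - ke) <= _KA_KE_TOL * p.ka:
        x = x0 * eke + a0 * p.ka * tau * eka
    else:
        x = x0 * eke + a0 * p.ka / (p.ka - ke) * (eke - eka)
    return x / p.v


def _segment_advance(p: IndividualPk, a0: float, x0: float, dt: float):
    """Propagate (depot, central) amounts over dt and return the segment AUC.

    The AUC is the exact integral of C over the segment:
    int X dt = x0*(1-e^{-ke dt})/ke + a0*ka/(ka-ke)*[(1-e^{-ke dt})/ke - (1-e^{-ka dt})/ka]
    """
    ke = p.ke
    eka = math.exp(-p.ka * dt)
    eke = math.exp(-ke * dt)
    gke = (1.0 - eke) / ke
    gka = (1.0 - eka) / p.ka
    if abs(p.ka - ke) <= _KA_KE_TOL * p.ka:
        x1 = x0 * eke + a0 * p.ka * dt * eka
        # limit of ka/(ka-ke)*(gke-gka) as ke->ka
        int_x = x0 * gke + a0 * (gka - dt * eka)
    else:
        fac = p.ka / (p.ka - ke)
        x1 = x0 * eke + a0 * fac * (eke - eka)
        int_x = x0 * gke + a0 * fac * (gke - gka)
    a1 = a0 * eka
    return a1, x1, int_x / p.v


def simulate_pk(
    p: IndividualPk, doses, grid, subject_id=None
) -> ConcProfile:
    """Concentration profile for an arbitrary dose schedule on ``grid``.

    Exact piecewise-analytic propagation of the linear system (identical to
    Bateman superposition but O(n_doses + n_grid) instead of the product).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    events = _sorted_events(doses)
    if events and events[0][0] < grid[0]:
        raise ValueError("dose before grid start")
    if events and events[-1][0] > grid[-1]:
        raise ValueError("grid must cover all dose times")

    conc = np.zeros_like(grid)
    if not events:
        return ConcProfile(times=grid, conc=conc, subject_id=subject_id)

    # segment boundaries: grid start, each dose time, grid end
    bounds = [grid[0]] + [t for t, _ in events] + [grid[-1]]
    amounts = {t: amt for t, amt in events}
    a, x = 0.0, 0.0
    for k in range(len(bounds) - 1):
        t0, t1 = bounds[k], bounds[k + 1]
        if t0 in amounts:
            a += p.f * amounts.pop(t0)
        lo = np.searchsorted(grid, t0, side="left")
        hi = np.searchsorted(grid, t1, side="right" if k == len(bounds) - 2 else "left")
        if hi > lo:
            conc[lo:hi] = _segment_conc(p, a, x, grid[lo:hi] - t0)
        if t1 > t0:
            a, x, _ = _segment_advance(p, a, x, t1 - t0)
    np.maximum(conc, 0.0, out=conc)
    return ConcProfile(times=grid, conc=conc, subject_id=subject_id)


def cumulative_auc(p: IndividualPk, doses, t: float) -> float:
    """Exact integral of the concentration curve over [0, t]."""
    if t < 0:
        raise ValueError("t must be >= 0")
    events = _sorted_events(doses)
    a, x, total, t_cur = 0.0, 0.0, 0.0, 0.0
    for et, amt in events:
        if et >= t:
            break
        if et > t_cur:
            a, x, seg = _segment_advance(p, a, x, et - t_cur)
            total += seg
            t_cur = et
        a += p.f * amt
    if t > t_cur:
        _, _, seg = _segment_advance(p, a, x, t - t_cur)
        total += seg
    return total


def auc_interval(p: IndividualPk, doses, t0: float, t1: float) -> float:
    """AUC of the concentration curve on [t0, t1] (conc*h), closed form."""
    if not t1 > t0:
        raise ValueError("t1 must be > t0")
    if t0 < 0:
        raise ValueError("interval outside simulated span (t0 < 0)")
    return cumulative_auc(p, doses, t1) - cumulative_auc(p, doses, t0)


def steady_state_conc(p: IndividualPk, dose: float, tau: float, t) -> np.ndarray | float:
    """Concentration at time ``t`` within a steady-state interval of length tau."""
    ke = p.ke
    if abs(p.ka - ke) <= _KA_KE_TOL * p.ka:
        raise ValueError("steady-state closed form requires ka != ke")
    t_arr = np.asarray(t, dtype=float)
    coef = p.f * dose * p.ka / (p.v * (p.ka - ke))
    acc_ke = 1.0 / (1.0 - math.exp(-ke * tau))
    acc_ka = 1.0 / (1.0 - math.exp(-p.ka * tau))
    c = coef * (np.exp(-ke * t_arr) * acc_ke - np.exp(-p.ka * t_arr) * acc_ka)
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def steady_state_auc_tau(p: IndividualPk, dose: float) -> float:
    """Steady-state dosing-interval AUC: the linear-PK identity F*D/CL."""
    return p.f * dose / p.cl
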