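"""Direct-effect growth-velocity model driven by dosing-interval AUC.

Growth velocity at treatment time t (years) is an Emax function of the AUC
over the dosing interval preceding the measurement, damped by a first-order
attenuation term that reproduces the universal decline of GV from the first
to the second treatment year at constant dose:

    GV(t) = [E0 + (Emax + eta) * AUCtau / (AUC50 + AUCtau)] * exp(-lam * t)

E0 is the subject's pre-treatment (baseline) growth velocity; eta is an
additive between-subject random effect on the drug-attributable capacity.
Height is the running integral of GV; "annualized GV" at month m is the
height gained over the preceding 12 months, i.e. (H(m) - H(m-12)) per year
(so the 24-month value is second-year velocity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import MONTH_H, YEAR_H, WEEK_H

__all__ = [
    "GvParams",
    "GrowthTrajectory",
    "instantaneous_gv",
    "integrate_height",
    "annualized_gv",
    "gv_attenuation_percent",
]


@dataclass(frozen=True)
class GvParams:
    """Growth-velocity model parameters.

    ``e0`` baseline GV (cm/year); ``emax_gv`` maximal drug-attributable GV
    (cm/year); ``auc50`` the interval AUC (conc*h) at half-maximal effect;
    ``lam`` first-order attenuation rate (1/year); ``omega_gv`` additive
    between-subject SD on the Emax term; ``sigma_gv`` additive residual SD on
    observed GV.
    """

    e0: float
    emax_gv: float
    auc50: float
    lam: float
    omega_gv: float = 0.0
    sigma_gv: float = 0.0

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValueError("GvParams.e0 must be >= 0")
        if self.emax_gv < 0:
            raise ValueError("GvParams.emax_gv must be >= 0")
        if not self.auc50 > 0:
            raise ValueError("GvParams.auc50 must be > 0")
        if self.lam < 0:
            raise ValueError("GvParams.lam must be >= 0")


@dataclass
class GrowthTrajectory:
    """Height and instantaneous GV over time (months)."""

    times: np.ndarray  # months
    height: np.ndarray  # cm
    inst_gv: np.ndarray  # cm/year

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.inst_gv = np.asarray(self.inst_gv, dtype=float)
        if np.any(np.diff(self.height) < -1e-9):
            raise ValueError("height must be non-decreasing")
        if np.any(self.inst_gv < -1e-12):
            raise ValueError("instantaneous GV must be >= 0")


def instantaneous_gv(gv: GvParams, auc_tau, t, eta: float = 0.0):
    """GV (cm/year) at treatment time ``t`` years given the preceding-interval AUC."""
    auc_arr = np.asarray(auc_tau, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(auc_arr < 0):
        raise ValueError("auc_tau must be >= 0")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    effect = gv.e0 + (gv.emax_gv + eta) * auc_arr / (gv.auc50 + auc_arr)
    out = np.maximum(effect, 0.0) * np.exp(-gv.lam * t_arr)
    scalar = np.isscalar(auc_tau) and np.isscalar(t)
    return float(out) if scalar else out


def integrate_height(gv_fn, h0: float, horizon_months: float, step_days: float = 7.0) -> GrowthTrajectory:
    """Trapezoidal integral of a GV function (cm/year vs years) from ``h0``.

    ``gv_fn`` maps time in years to instantaneous GV in cm/year.
    """
    if not horizon_months > 0:
        raise ValueError("horizon must be > 0")
    if not step_days > 0:
        raise ValueError("step must be > 0")
    horizon_h = horizon_months * MONTH_H
    step_h = step_days * 24.0
    n = int(np.ceil(horizon_h / step_h))
    t_h = np.minimum(np.arange(n + 1) * step_h, horizon_h)
    t_y = t_h / YEAR_H
    gv = np.asarray([float(gv_fn(ty)) for ty in t_y])
    if np.any(gv < 0):
        raise ValueError("gv_fn returned a negative velocity")
    gains = np.concatenate([[0.0], np.cumsum(0.5 * (gv[:-1] + gv[1:]) * np.diff(t_y))])
    return GrowthTrajectory(times=t_h / MONTH_H, height=h0 + gains, inst_gv=gv)


def annualized_gv(traj: GrowthTrajectory, at_month: float) -> float:
    """Height gained over the 12 months preceding ``at_month``, in cm/year."""
    lo, hi = at_month - 12.0, at_month
    if lo < traj.times[0] - 1e-9 or hi > traj.times[-1] + 1e-9:
        raise ValueError(
            f"annualization window [{lo}, {hi}] months outside trajectory span"
        )
    h_lo = float(np.interp(lo, traj.times, traj.height))
    h_hi = float(np.interp(hi, traj.times, traj.height))
    return h_hi - h_lo


def gv_attenuation_percent(gv_year1: float, gv_year2: float) -> float:
    """Percent reduction of annualized GV from the first to the second year."""
    if not gv_year1 > 0:
        raise ValueError("first-year GV must be > 0")
    return 100.0 * (gv_year1 - gv_year2) / gv_year1
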