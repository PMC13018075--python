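"""Dose-schedule builders: quarterly up-titration, weight bands, weekly regimens.

The up-titration schedule starts at 0.14 mg/kg/week and multiplies by
(1 + rate) every 3 months, rounding half-up to 2 decimal places of the
unrounded compound value and capping at 0.28 mg/kg/week.  Weight-banded
dosing maps each product strength (2-5 mg in 0.5 mg steps) to a target
weight strength/0.14 and a wide (+/- 3.57 kg = 0.5 mg / 0.14 mg/kg) and
narrow (+/- 1.78 kg) band; band arithmetic is performed on the 2-dp rounded
target values, matching the printed convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

import numpy as np

from .pk import DoseEvent
from .units import MONTH_H, WEEK_H

__all__ = [
    "DEFAULT_STRENGTHS",
    "TitrationPlan",
    "StrengthBand",
    "StrengthAssignment",
    "Regimen",
    "CapNotReachedError",
    "uptitration_schedule",
    "months_to_cap",
    "band_edges",
    "assign_strength",
    "weekly_regimen",
]

DEFAULT_STRENGTHS = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


def _round(x: float, nd: int, mode=ROUND_HALF_UP) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-nd), rounding=mode))


class CapNotReachedError(RuntimeError):
    """The titration cap is not reached within the searched horizon."""


@dataclass(frozen=True)
class TitrationPlan:
    """Quarterly up-titration plan in unit-dose (mg/kg/week) space."""

    start_unit_dose: float = 0.14
    rate: float = 0.123
    step_months: int = 3
    cap: float = 0.28
    rounding: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.start_unit_dose <= self.cap:
            raise ValueError("need 0 < start_unit_dose <= cap")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.step_months <= 0:
            raise ValueError("step_months must be > 0")


@dataclass(frozen=True)
class StrengthBand:
    """A product strength with its target weight and band edges (kg)."""

    strength: float
    target_wt: float
    lo_wide: float
    lo_narrow: float
    hi_narrow: float
    hi_wide: float

    def __post_init__(self) -> None:
        if not (self.lo_wide < self.lo_narrow < self.target_wt < self.hi_narrow < self.hi_wide):
            raise ValueError("band edges must be strictly ordered around the target weight")

    @property
    def scenario_weights(self) -> tuple[float, ...]:
        """The five simulated body weights: -wide, -narrow, target, +narrow, +wide."""
        return (self.lo_wide, self.lo_narrow, self.target_wt, self.hi_narrow, self.hi_wide)


@dataclass(frozen=True)
class StrengthAssignment:
    strength: float
    out_of_range: bool = False


@dataclass
class Regimen:
    """A weekly dosing plan over the simulation horizon.

    Either a concrete event list (``events``) or a dosing policy resolved at
    simulation time: a quarterly unit-dose schedule (mg/kg/week, re-applied to
    the most recent quarterly weight) or a fixed product strength in mg.
    """

    provenance: str  # "weight-based" | "titrated" | "fixed-strength"
    events: list[DoseEvent] | None = None
    unit_schedule: tuple[float, ...] | None = None  # per quarter, mg/kg/week
    step_months: int = 3
    fixed_strength: float | None = None

    def __post_init__(self) -> None:
        if self.events is not None:
            times = [e.time for e in self.events]
            if any(abs(b - a - WEEK_H) > 1e-9 for a, b in zip(times, times[1:])):
                raise ValueError("inter-dose interval must be exactly 168 h")

    def unit_dose_at_month(self, month: float) -> float:
        if self.unit_schedule is None:
            raise ValueError("regimen has no unit-dose schedule")
        idx = min(int(month // self.step_months), len(self.unit_schedule) - 1)
        return self.unit_schedule[idx]


def uptitration_schedule(plan: TitrationPlan, horizon_months: int = 24) -> list[float]:
    """Quarterly unit doses (mg/kg/week) at months 0, 3, ..., horizon.

    Dose at quarter k is min(round(start * (1+rate)^k, 2), cap); once the cap
    is reached the dose is held there.
    """
    if horizon_months % plan.step_months != 0:
        raise ValueError("horizon must be a multiple of step_months")
    n_steps = horizon_months // plan.step_months
    doses: list[float] = []
    capped = False
    for k in range(n_steps + 1):
        if capped:
            doses.append(plan.cap)
            continue
        d = _round(plan.start_unit_dose * (1.0 + plan.rate) ** k, plan.rounding)
        if d >= plan.cap:
            d = plan.cap
            capped = True
        doses.append(d)
    return doses


def months_to_cap(plan: TitrationPlan, search_horizon_months: int = 240) -> int:
    """First month at which the titration schedule reaches the cap."""
    if plan.rate == 0 and plan.start_unit_dose < plan.cap:
        raise CapNotReachedError("zero rate never reaches the cap")
    schedule = uptitration_schedule(plan, horizon_months=search_horizon_months)
    for k, d in enumerate(schedule):
        if d >= plan.cap:
            return k * plan.step_months
    raise CapNotReachedError(
        f"cap {plan.cap} not reached within {search_horizon_months} months"
    )


def band_edges(strength: float, unit_dose: float = 0.14, wide: float | None = None) -> StrengthBand:
    """Target weight and band edges for one product strength.

    The wide half-width defaults to round(0.5/unit_dose, 2) kg (the 0.5 mg
    strength increment expressed in weight); the narrow half-width is half of
    that, rounded half-to-even to 2 dp (1.785 -> 1.78 as printed).  All edge
    arithmetic uses the 2-dp rounded values.
    """
    if not strength > 0:
        raise ValueError("strength must be > 0")
    if wide is None:
        wide = _round(0.5 / unit_dose, 2)
    narrow = _round(wide / 2.0, 2, mode=ROUND_HALF_EVEN)
    target = _round(strength / unit_dose, 2)
    dec = lambda x: Decimal(repr(x))  # noqa: E731  exact 2-dp arithmetic
    return StrengthBand(
        strength=strength,
        target_wt=target,
        lo_wide=float(dec(target) - dec(wide)),
        lo_narrow=float(dec(target) - dec(narrow)),
        hi_narrow=float(dec(target) + dec(narrow)),
        hi_wide=float(dec(target) + dec(wide)),
    )


def assign_strength(
    weight: float, strengths=DEFAULT_STRENGTHS, unit_dose: float = 0.14
) -> StrengthAssignment:
    """Product strength whose target weight is nearest; ties go to the lower strength."""
    if not weight > 0:
        raise ValueError("weight must be > 0")
    bands = [band_edges(s, unit_dose=unit_dose) for s in sorted(strengths)]
    # distances rounded to 9 dp so exact half-gap weights tie cleanly in floats
    best = min(bands, key=lambda b: (round(abs(weight - b.target_wt), 9), b.strength))
    in_any_wide = any(b.lo_wide <= weight <= b.hi_wide for b in bands)
    return StrengthAssignment(strength=best.strength, out_of_range=not in_any_wide)


def weekly_regimen(
    unit_dose_schedule,
    weight_series,
    horizon_months: float,
    step_months: int = 3,
    fixed_strength: float | None = None,
) -> Regimen:
    """Concrete weekly dose events over the horizon.

    ``unit_dose_schedule`` gives mg/kg/week per quarter and ``weight_series``
    the body weight (kg) at each quarterly visit; the weekly dose in mg is
    the current unit dose times the weight at the most recent visit.  For a
    fixed-strength regimen the weekly dose equals the strength regardless of
    weight.
    """
    horizon_h = horizon_months * MONTH_H
    n_weeks = int(np.ceil(horizon_h / WEEK_H))
    events: list[DoseEvent] = []
    weights = None if weight_series is None else list(weight_series)
    if weights is not None and any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    for k in range(n_weeks):
        t = k * WEEK_H
        if fixed_strength is not None:
            amt = fixed_strength
        else:
            month = t / MONTH_H
            q = min(int(month // step_months), len(unit_dose_schedule) - 1)
            if weights is None or q >= len(weights):
                raise ValueError("weight series must be defined at each quarterly visit")
            amt = unit_dose_schedule[q] * weights[q]
        events.append(DoseEvent(time=t, amount=amt))
    provenance = "fixed-strength" if fixed_strength is not None else "weight-based"
    return Regimen(provenance=provenance, events=events)
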