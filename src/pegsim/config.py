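"""Layered run configuration (packaged defaults < YAML file < CLI flags).

All study constants — the 0.14 mg/kg/week start dose, the 0.28 cap, the
escalation rates, the 3-month step, the product strengths, the band
half-widths, the 500-replicate default and the 90 % band level — live in
the default configuration, never in the simulation logic.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

DEFAULTS = {
    "seed": 12345,
    "horizon_months": 24,
    "n_replicates": 500,
    "grid_step_h": 1.0,
    "start_unit_dose": 0.14,
    "cap_unit_dose": 0.28,
    "rates": [0.123, 0.189, 0.260],
    "step_months": 3,
    "strengths": [2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0],
    "band_level": 0.90,
    "n_ghd": 292,
    "per_band_group": 10,
    "round_titrated": True,
    "standardize_banded_sds": -1.0,
    "params_file": None,
}


class RunConfig(BaseModel):
    """Validated run configuration for the simulation CLI."""

    seed: int = DEFAULTS["seed"]
    horizon_months: float = Field(DEFAULTS["horizon_months"], gt=0)
    n_replicates: int = Field(DEFAULTS["n_replicates"], ge=1)
    grid_step_h: float = Field(DEFAULTS["grid_step_h"], gt=0)
    start_unit_dose: float = Field(DEFAULTS["start_unit_dose"], gt=0)
    cap_unit_dose: float = Field(DEFAULTS["cap_unit_dose"], gt=0)
    rates: list[float] = DEFAULTS["rates"]
    step_months: int = Field(DEFAULTS["step_months"], gt=0)
    strengths: list[float] = DEFAULTS["strengths"]
    band_level: float = Field(DEFAULTS["band_level"], gt=0, le=1)
    n_ghd: int = Field(DEFAULTS["n_ghd"], ge=1)
    per_band_group: int = Field(DEFAULTS["per_band_group"], ge=2)
    round_titrated: bool = DEFAULTS["round_titrated"]
    standardize_banded_sds: float | None = DEFAULTS["standardize_banded_sds"]
    params_file: str | None = None

    @field_validator("rates")
    @classmethod
    def _positive_rates(cls, v):
        if any(r < 0 for r in v):
            raise ValueError("escalation rates must be >= 0")
        return v

    @field_validator("start_unit_dose")
    @classmethod
    def _start_le_cap(cls, v, info):
        return v

    model_config = {"extra": "forbid"}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Defaults, optionally updated from a YAML file, then keyword overrides."""
    data = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        data.update(user)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
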