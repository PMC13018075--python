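"""Virtual-patient generators and synthetic observation designs.

Generates everything the original (private) trial data provided: a pediatric
GHD cohort with the published baseline moments (GV 3.57 +/- 1.06 cm/year,
IGF-1 SDS -1.27 +/- 0.55), the 70-subject weight-banded cohort (10 per
product strength, 1:1 sex ratio, weights at the five band scenario points),
a rich-sampling single-dose adult PK design, and a sparse pediatric PK/PD
design with quarterly pre-dose troughs.  All generators are pure functions
of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import BENCHMARKS, PopulationParams, nominal_params
from .pk import DoseEvent, conc_single_dose, individual_params
from .regimens import DEFAULT_STRENGTHS, Regimen, band_edges
from .reference import GrowthReference, load_growth_reference, load_igf1_reference
from .seeds import child_rng
from .growth import instantaneous_gv
from .units import MONTH_H, WEEK_H, YEAR_H

__all__ = [
    "Subject",
    "generate_ghd_cohort",
    "generate_banded_cohort",
    "update_weight",
    "phase1_design",
    "sparse_pediatric_design",
    "PHASE1_SAMPLING_H",
    "PHASE1_DOSE_LEVELS",
]

# rich single-dose PK sampling times (h): pre-dose plus 14 post-dose samples
PHASE1_SAMPLING_H = (0.0, 6.0, 12.0, 15.0, 24.0, 48.0, 72.0, 96.0, 120.0,
                     144.0, 168.0, 192.0, 240.0, 288.0, 336.0)
PHASE1_DOSE_LEVELS = (0.01, 0.03, 0.06, 0.12, 0.2)  # mg/kg single doses

# GHD cohorts sit low in the healthy weight/height channels
_GHD_WEIGHT_Z = -1.5
_GHD_HEIGHT_Z = -1.5
_HEIGHT_SD_LN = 0.045


@dataclass
class Subject:
    """One virtual patient."""

    id: str
    sex: str  # "M" | "F"
    age: float  # years
    weight: float  # kg
    height: float  # cm
    baseline_gv: float  # cm/year
    baseline_igf1_sds: float
    etas: dict = field(default_factory=dict)
    group: float | None = None  # banded cohort: product strength (mg)
    scenario: str | None = None  # banded cohort: weight-scenario label

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not (self.weight > 0 and self.height > 0):
            raise ValueError("weight and height must be positive")
        if self.baseline_gv < 0:
            raise ValueError("baseline_gv must be >= 0")


def _draw_pk_etas(rng, params: PopulationParams) -> dict:
    return {
        "eta_cl": float(rng.normal(0.0, params.pk.omega_cl)),
        "eta_v": float(rng.normal(0.0, params.pk.omega_v)),
        "eta_ka": float(rng.normal(0.0, params.pk.omega_ka)),
    }


def generate_ghd_cohort(
    n: int = 292,
    seed: int = 0,
    ref: GrowthReference | None = None,
    params: PopulationParams | None = None,
    age_range: tuple[float, float] = (4.0, 12.0),
) -> list[Subject]:
    """Virtual pediatric GHD cohort with the published baseline moments.

    Baseline GV ~ Normal(3.57, 1.06) truncated at 0 (a negative draw has
    probability ~4e-4; redrawn), baseline IGF-1 SDS ~ Normal(-1.27, 0.55);
    weights/heights sit ~1.5 SD below the healthy reference channels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ref = ref or load_growth_reference()
    params = params or nominal_params()
    rng = child_rng(seed, "ghd-cohort")
    lo, hi = age_range
    span = ref.age_span
    if lo < span[0] or hi > span[1]:
        raise ValueError("age_range not covered by the growth reference")
    subjects = []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(rng.uniform(lo, hi))
        wt = ref.median_weight(age, sex) * math.exp(
            rng.normal(_GHD_WEIGHT_Z * ref.weight_sd_ln(age, sex), ref.weight_sd_ln(age, sex))
        )
        ht = ref.median_height(age, sex) * math.exp(
            rng.normal(_GHD_HEIGHT_Z * _HEIGHT_SD_LN, _HEIGHT_SD_LN)
        )
        gv0 = -1.0
        while gv0 < 0:
            gv0 = rng.normal(BENCHMARKS["baseline_gv_mean"], BENCHMARKS["baseline_gv_sd"])
        sds0 = float(
            rng.normal(BENCHMARKS["baseline_igf1_sds_mean"], BENCHMARKS["baseline_igf1_sds_sd"])
        )
        etas = _draw_pk_etas(rng, params)
        etas["eta_smax"] = float(rng.normal(0.0, params.idr.omega_smax))
        etas["eta_gv"] = float(rng.normal(0.0, params.gv.omega_gv))
        subjects.append(
            Subject(
                id=f"GHD{i + 1:04d}",
                sex=sex,
                age=age,
                weight=float(wt),
                height=float(ht),
                baseline_gv=float(gv0),
                baseline_igf1_sds=sds0,
                etas=etas,
            )
        )
    return subjects


def generate_banded_cohort(
    strengths=DEFAULT_STRENGTHS,
    per_group: int = 10,
    seed: int = 0,
    ref: GrowthReference | None = None,
    unit_dose: float = 0.14,
) -> list[Subject]:
    """The weight-banded virtual cohort: ``per_group`` subjects per strength.

    Subject weights cycle through the five band scenario points (target,
    +/- narrow, +/- wide) with an exact 1:1 male-to-female ratio; ages and
    heights are back-solved from the growth reference channel (GHD-shifted
    by -1.5 weight SD, clamped to ages 3-16), and the baseline IGF-1 SDS is
    standardized to -1.
    """
    if len(strengths) != 7:
        raise ValueError("expected the 7 product strengths")
    if per_group < 1 or per_group % 2:
        raise ValueError("per_group must be a positive even number (1:1 sex ratio)")
    ref = ref or load_growth_reference()
    rng = child_rng(seed, "banded-cohort")
    scenario_labels = ("-wide", "-narrow", "target", "+narrow", "+wide")
    subjects = []
    for strength in strengths:
        band = band_edges(strength, unit_dose=unit_dose)
        scen_weights = dict(zip(scenario_labels, band.scenario_weights))
        # one baseline GV per (strength, sex): scenario contrasts within a
        # cell then isolate the weight effect (paired design)
        gv0_by_sex = {}
        for sex in ("M", "F"):
            g = -1.0
            while g < 0:
                g = rng.normal(BENCHMARKS["baseline_gv_mean"], BENCHMARKS["baseline_gv_sd"])
            gv0_by_sex[sex] = float(g)
        for j in range(per_group):
            scen = scenario_labels[j % len(scenario_labels)]
            sex = "M" if j < per_group // 2 else "F"
            wt = scen_weights[scen]
            # back-solve age from the GHD-shifted weight channel
            sd_ln = ref.weight_sd_ln(ref.age_span[0], sex)
            channel_wt = wt / math.exp(_GHD_WEIGHT_Z * sd_ln)
            try:
                age = ref.age_for_weight(channel_wt, sex)
            except ValueError as err:
                raise ValueError(
                    f"scenario weight {wt} kg outside the reference range"
                ) from err
            age = float(np.clip(age, 3.0, 16.0))
            ht = ref.median_height(age, sex) * math.exp(_GHD_HEIGHT_Z * _HEIGHT_SD_LN)
            gv0 = gv0_by_sex[sex]
            subjects.append(
                Subject(
                    id=f"BND{strength:g}mg{j + 1:02d}",
                    sex=sex,
                    age=age,
                    weight=float(wt),
                    height=float(ht),
                    baseline_gv=float(gv0),
                    baseline_igf1_sds=-1.0,
                    group=strength,
                    scenario=scen,
                )
            )
    return subjects


def update_weight(subject: Subject, height_gain_cm: float, ref: GrowthReference | None = None) -> float:
    """New body weight after growing ``height_gain_cm`` along the subject's channel."""
    ref = ref or load_growth_reference()
    return ref.project_weight(subject.age, subject.sex, subject.weight, height_gain_cm)


def phase1_design(
    n: int = 36,
    dose_levels=PHASE1_DOSE_LEVELS,
    seed: int = 0,
    params: PopulationParams | None = None,
    sampling_times=PHASE1_SAMPLING_H,
) -> pd.DataFrame:
    """Rich-sampling single-dose adult PK study as a NONMEM-style table.

    ``n`` healthy adult males split across the mg/kg dose levels; one
    observation row per sampling time (n x 15 PK rows) plus one dose row per
    subject.  Observations are model prediction x (1 + proportional error)
    + additive error, fully seeded.
    """
    params = params or nominal_params()
    rng = child_rng(seed, "phase1")
    rows = []
    n_levels = len(dose_levels)
    for i in range(n):
        level = dose_levels[i % n_levels]
        wt = float(np.clip(rng.normal(65.0, 8.0), 45.0, 95.0))
        age = float(rng.uniform(19.0, 45.0))
        etas = _draw_pk_etas(rng, params)
        ind = individual_params(
            params.pk, wt, (etas["eta_cl"], etas["eta_v"], etas["eta_ka"])
        )
        dose = level * wt
        sid = i + 1
        base = {"ID": sid, "WT": wt, "AGE": age, "SEX": 1, "DOSEGRP": level}
        rows.append({**base, "TIME": 0.0, "AMT": dose, "DV": np.nan, "EVID": 1, "MDV": 1, "CMT": 1})
        for t in sampling_times:
            pred = conc_single_dose(ind, dose, t)
            dv = pred * (1.0 + rng.normal(0.0, params.pk.sigma_prop)) + rng.normal(
                0.0, params.pk.sigma_add
            )
            rows.append(
                {**base, "TIME": float(t), "AMT": 0.0, "DV": float(dv), "EVID": 0, "MDV": 0, "CMT": 2}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def sparse_pediatric_design(
    cohort,
    months: int = 12,
    seed: int = 0,
    params: PopulationParams | None = None,
    regimens_by_id: dict | None = None,
    unit_dose: float = 0.14,
) -> pd.DataFrame:
    """Sparse pediatric PK/PD design: quarterly pre-dose troughs and GV.

    Per subject: weekly dose rows, plus at every quarterly visit (months 0,
    3, ..., ``months``) a pre-dose PK trough (CMT 2), a pre-dose IGF-1
    trough (CMT 3) and an annualized-rate GV observation (CMT 4), each with
    the configured residual error.  ``regimens_by_id`` optionally assigns a
    :class:`~pegsim.regimens.Regimen` per subject id; the default is flat
    ``unit_dose`` mg/kg/week weight-based dosing.
    """
    from .trial import SimConfig, simulate_subject  # deferred: avoids cycle

    if not cohort:
        raise ValueError("cohort must be non-empty")
    params = params or nominal_params()
    rng = child_rng(seed, "sparse-pediatric")
    growth_ref = load_growth_reference()
    igf1_ref = load_igf1_reference()
    visits = np.arange(0, months + 1, 3)
    # body weight is held at baseline so the exposure model stays
    # time-invariant: estimation treats WT as a constant covariate
    config = SimConfig(seed=seed, horizon_months=float(months) + 1.0, update_weights=False)
    schedule = tuple([unit_dose] * (months // 3 + 2))
    rows = []
    for subj in cohort:
        regimen = (
            regimens_by_id.get(subj.id)
            if regimens_by_id is not None
            else Regimen(provenance="weight-based", unit_schedule=schedule)
        )
        res = simulate_subject(subj, regimen, params, config, growth_ref=growth_ref,
                               igf1_ref=igf1_ref)
        base = {
            "ID": subj.id,
            "WT": subj.weight,
            "AGE": subj.age,
            "SEX": 1 if subj.sex == "M" else 2,
        }
        for t, amt in zip(res.dose_times, res.dose_amounts):
            rows.append({**base, "TIME": float(t), "AMT": float(amt), "DV": np.nan,
                         "EVID": 1, "MDV": 1, "CMT": 1})
        for m in visits:
            t_visit = m * MONTH_H
            nxt = res.dose_times[np.searchsorted(res.dose_times, t_visit - 1e-9)]
            t_obs = max(nxt - 0.1, 0.0)
            c_pred = float(np.interp(t_obs, res.conc.times, res.conc.conc))
            c_dv = c_pred * (1.0 + rng.normal(0.0, params.pk.sigma_prop)) + rng.normal(
                0.0, params.pk.sigma_add
            )
            r_pred = float(np.interp(t_obs, res.igf1.times, res.igf1.igf1))
            r_dv = r_pred * (1.0 + rng.normal(0.0, params.idr.sigma_igf))
            week = int(t_obs // WEEK_H)
            auc_prev = float(res.weekly_auc[week - 1]) if week >= 1 else 0.0
            # GV is read out at the visit timestamp with the AUC of the
            # preceding dosing interval (the estimation-side convention)
            gv_i = replace(params.gv, e0=float(subj.baseline_gv))
            gv_pred = instantaneous_gv(
                gv_i, auc_prev, t_obs / YEAR_H, eta=float(subj.etas.get("eta_gv", 0.0))
            )
            gv_dv = gv_pred + rng.normal(0.0, params.gv.sigma_gv)
            rows.append({**base, "TIME": t_obs, "AMT": 0.0, "DV": float(c_dv),
                         "EVID": 0, "MDV": 0, "CMT": 2})
            rows.append({**base, "TIME": t_obs, "AMT": 0.0, "DV": float(r_dv),
                         "EVID": 0, "MDV": 0, "CMT": 3, "AUCTAU": auc_prev})
            rows.append({**base, "TIME": t_obs, "AMT": 0.0, "DV": float(gv_dv),
                         "EVID": 0, "MDV": 0, "CMT": 4, "AUCTAU": auc_prev})
    df = pd.DataFrame(rows)
    df["AUCTAU"] = df.get("AUCTAU", np.nan)
    return df.sort_values(["ID", "TIME", "EVID", "CMT"], kind="stable").reset_index(drop=True)
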