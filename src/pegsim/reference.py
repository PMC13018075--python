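"""Synthetic age/sex reference tables for IGF-1 and growth.

Both tables are SYNTHETIC stand-ins: smooth, monotone, plausibly scaled
curves for children aged 2-18 y.  They exist so that the SDS standardization
and weight-for-age channel logic can run end to end; they are NOT clinical
reference data and must not be used for any real-patient calculation.  All
downstream code depends only on the lookup interface, so a real reference
can be dropped in by replacing the CSVs.

Tables ship as packaged CSVs (``data/igf1_reference.csv`` with columns
age, sex, mu_ln, sd_ln and ``data/growth_reference.csv`` with columns
age, sex, weight_median, weight_sd_ln, height_median) and are linearly
interpolated in age.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .igf1 import Igf1Reference

__all__ = [
    "GrowthReference",
    "load_igf1_reference",
    "load_growth_reference",
    "build_igf1_table",
    "build_growth_table",
]

_AGES = np.arange(2.0, 18.5, 1.0)

# Synthetic IGF-1 medians (ng/mL) per integer age; lognormal spread sd_ln = 0.35.
_IGF1_MEDIAN = {
    "M": [60, 70, 85, 100, 115, 130, 150, 170, 190, 215, 245, 280, 320, 350, 370, 380, 380],
    "F": [65, 80, 95, 110, 130, 150, 170, 195, 225, 260, 300, 340, 370, 385, 390, 385, 380],
}
_IGF1_SD_LN = 0.35

# Synthetic weight (kg) and height (cm) medians; weight spread sd_ln = 0.13.
_WEIGHT_MEDIAN = {
    "M": [12.5, 14.7, 16.7, 18.9, 21.3, 24.1, 27.3, 30.5, 33.8, 37.5, 41.6, 46.5,
          51.6, 56.0, 59.3, 61.5, 63.0],
    "F": [11.9, 14.1, 16.2, 18.3, 20.6, 23.3, 26.4, 29.9, 33.9, 38.2, 42.5, 46.3,
          49.4, 51.6, 53.0, 53.8, 54.2],
}
_HEIGHT_MEDIAN = {
    "M": [88.5, 96.8, 104.1, 111.3, 117.7, 124.0, 130.0, 135.4, 140.2, 145.3, 151.9,
          159.5, 165.9, 169.8, 171.6, 172.3, 172.7],
    "F": [87.2, 95.6, 103.1, 110.2, 116.6, 122.5, 128.5, 134.1, 140.1, 146.6, 152.4,
          156.3, 158.6, 159.8, 160.1, 160.3, 160.6],
}
_WEIGHT_SD_LN = 0.13


def build_igf1_table() -> pd.DataFrame:
    rows = []
    for sex in ("M", "F"):
        for age, med in zip(_AGES, _IGF1_MEDIAN[sex]):
            rows.append(
                {"age": age, "sex": sex, "mu_ln": float(np.log(med)), "sd_ln": _IGF1_SD_LN}
            )
    return pd.DataFrame(rows)


def build_growth_table() -> pd.DataFrame:
    rows = []
    for sex in ("M", "F"):
        for age, wt, ht in zip(_AGES, _WEIGHT_MEDIAN[sex], _HEIGHT_MEDIAN[sex]):
            rows.append(
                {
                    "age": age,
                    "sex": sex,
                    "weight_median": wt,
                    "weight_sd_ln": _WEIGHT_SD_LN,
                    "height_median": ht,
                }
            )
    return pd.DataFrame(rows)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("pegsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


class GrowthReference:
    """Weight-for-age / height-for-age channel lookup (linear in age).

    Subjects are assumed to keep a constant multiplicative offset from the
    median weight channel and a constant additive-in-log offset from the
    height channel, so growth moves them along their own percentile track.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "weight_median", "weight_sd_ln", "height_median"}
        if not required.issubset(table.columns):
            raise ValueError(f"growth table must have columns {sorted(required)}")
        self._by_sex = {}
        for sex, sub in table.groupby("sex"):
            sub = sub.sort_values("age")
            ages = sub["age"].to_numpy(dtype=float)
            wt = sub["weight_median"].to_numpy(dtype=float)
            ht = sub["height_median"].to_numpy(dtype=float)
            if np.any(np.diff(wt) <= 0) or np.any(np.diff(ht) <= 0):
                raise ValueError("reference medians must increase with age")
            self._by_sex[sex] = (ages, wt, ht, sub["weight_sd_ln"].to_numpy(dtype=float))

    @property
    def age_span(self) -> tuple[float, float]:
        lo = max(v[0][0] for v in self._by_sex.values())
        hi = min(v[0][-1] for v in self._by_sex.values())
        return lo, hi

    def _tables(self, sex):
        if sex not in self._by_sex:
            raise KeyError(f"unknown sex {sex!r}")
        return self._by_sex[sex]

    def _check_age(self, age, sex):
        ages = self._tables(sex)[0]
        if np.any(np.asarray(age) < ages[0]) or np.any(np.asarray(age) > ages[-1]):
            raise ValueError(f"age {age} outside growth reference span for sex {sex!r}")

    def median_weight(self, age, sex) -> float:
        self._check_age(age, sex)
        ages, wt, _, _ = self._tables(sex)
        return float(np.interp(age, ages, wt))

    def median_height(self, age, sex) -> float:
        self._check_age(age, sex)
        ages, _, ht, _ = self._tables(sex)
        return float(np.interp(age, ages, ht))

    def weight_sd_ln(self, age, sex) -> float:
        self._check_age(age, sex)
        ages, _, _, sd = self._tables(sex)
        return float(np.interp(age, ages, sd))

    def age_for_weight(self, weight, sex) -> float:
        """Age whose median weight equals ``weight`` (inverse interpolation)."""
        ages, wt, _, _ = self._tables(sex)
        if not wt[0] <= weight <= wt[-1]:
            raise ValueError(
                f"weight {weight} kg outside reference channel [{wt[0]}, {wt[-1]}] for {sex!r}"
            )
        return float(np.interp(weight, wt, ages))

    def age_for_height(self, height, sex) -> float:
        ages, _, ht, _ = self._tables(sex)
        if not ht[0] <= height <= ht[-1]:
            raise ValueError(f"height {height} cm outside reference channel for {sex!r}")
        return float(np.interp(height, ht, ages))

    def project_weight(
        self, age0: float, sex: str, weight0: float, height_gain: float
    ) -> float:
        """Weight after growing ``height_gain`` cm along the subject's channel.

        The subject keeps a constant additive offset from the height-for-age
        median and a constant multiplicative offset from the weight-for-age
        median; the new 'height age' is found on the median curve and the
        weight ratio between the two ages is applied.  Ages beyond the table
        are clamped to its upper edge.
        """
        if height_gain < 0:
            raise ValueError("height_gain must be >= 0")
        ages, wt, ht, _ = self._tables(sex)
        self._check_age(age0, sex)
        h_med0 = float(np.interp(age0, ages, ht))
        target = min(h_med0 + height_gain, ht[-1])
        a1 = max(float(np.interp(target, ht, ages)), age0)
        w_ratio = float(np.interp(a1, ages, wt)) / float(np.interp(age0, ages, wt))
        return weight0 * w_ratio


def load_igf1_reference() -> Igf1Reference:
    return Igf1Reference(_read_packaged("igf1_reference.csv"))


def load_growth_reference() -> GrowthReference:
    return GrowthReference(_read_packaged("growth_reference.csv"))
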