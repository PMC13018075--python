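"""Trial simulation engine: subject chains, bands, replicate studies."""

import numpy as np
import pytest
from dataclasses import replace

from pegsim.cohort import Subject
from pegsim.regimens import Regimen, weekly_regimen
from pegsim.trial import (
    Band,
    SimConfig,
    band_overlap,
    prediction_band,
    run_banded_study,
    simulate_subject,
)
from pegsim.units import WEEK_H, YEAR_H


@pytest.fixture()
def subject():
    return Subject(
        id="S1", sex="M", age=8.0, weight=25.0, height=120.0,
        baseline_gv=3.57, baseline_igf1_sds=-1.27,
        etas={"eta_cl": 0.0, "eta_v": 0.0, "eta_ka": 0.0, "eta_smax": 0.0, "eta_gv": 0.0},
    )


def _fixed_regimen(strength):
    return Regimen(provenance="fixed-strength", fixed_strength=strength)


class TestSimulateSubject:
    def test_zero_dose_limits(self, subject, params):
        reg = Regimen(provenance="fixed-strength", fixed_strength=0.0)
        cfg = SimConfig(seed=0, horizon_months=24.0, update_weights=False)
        res = simulate_subject(subject, reg, params, cfg)
        # no drug: GV decays from baseline with the attenuation term only
        expected = subject.baseline_gv * np.exp(-params.gv.lam * res.dose_times / YEAR_H)
        assert np.allclose(res.weekly_gv, expected, rtol=1e-9)
        # IGF-1 SDS stays at the standardized baseline
        assert np.allclose(res.igf1.sds, -1.27, atol=1e-9)
        assert np.all(res.conc.conc == 0.0)

    def test_dose_doubling_doubles_auc_but_not_gv(self, subject, params):
        cfg = SimConfig(seed=0, horizon_months=12.0, update_weights=False)
        r1 = simulate_subject(subject, _fixed_regimen(3.5), params, cfg)
        r2 = simulate_subject(subject, _fixed_regimen(7.0), params, cfg)
        assert np.allclose(r2.weekly_auc, 2 * r1.weekly_auc, rtol=1e-9)
        g1 = r1.weekly_gv[-1] - subject.baseline_gv * np.exp(
            -params.gv.lam * r1.dose_times[-1] / YEAR_H
        )
        g2 = r2.weekly_gv[-1] - subject.baseline_gv * np.exp(
            -params.gv.lam * r2.dose_times[-1] / YEAR_H
        )
        assert g1 < g2 < 2 * g1  # Emax concavity

    def test_fixed_strength_equals_weight_based_at_target(self, subject, params):
        # 3.5 mg fixed vs 0.14 mg/kg at exactly 25.00 kg with frozen weight
        cfg = SimConfig(seed=0, horizon_months=12.0, update_weights=False)
        fixed = simulate_subject(subject, _fixed_regimen(3.5), params, cfg)
        based = simulate_subject(
            subject,
            Regimen(provenance="weight-based", unit_schedule=(0.14,) * 5),
            params,
            cfg,
        )
        assert np.allclose(fixed.conc.conc, based.conc.conc, rtol=1e-12)
        assert np.allclose(fixed.weekly_gv, based.weekly_gv, rtol=1e-12)

    def test_weight_update_feeds_back_into_dosing(self, subject, params, growth_ref):
        cfg_on = SimConfig(seed=0, horizon_months=24.0, update_weights=True)
        cfg_off = SimConfig(seed=0, horizon_months=24.0, update_weights=False)
        reg = Regimen(provenance="weight-based", unit_schedule=(0.14,) * 9)
        on = simulate_subject(subject, reg, params, cfg_on, growth_ref=growth_ref)
        off = simulate_subject(subject, reg, params, cfg_off)
        assert on.dose_amounts[-1] > off.dose_amounts[-1]
        assert np.all(np.diff(on.quarterly_weights) >= 0)

    def test_height_is_integral_of_gv(self, subject, params):
        cfg = SimConfig(seed=0, horizon_months=12.0, update_weights=False)
        res = simulate_subject(subject, _fixed_regimen(3.5), params, cfg)
        gain = np.sum(res.weekly_gv) * WEEK_H / YEAR_H
        assert res.growth.height[-1] - res.growth.height[0] == pytest.approx(gain)


class TestPredictionBand:
    def test_constant_replicates_zero_width(self):
        band = prediction_band(np.full((10, 5), 3.0))
        assert np.all(band.lower == band.upper)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(0.0, 1.0, (100_000, 1))
        band = prediction_band(draws, level=0.90)
        assert band.lower[0] == pytest.approx(-1.6449, abs=0.02)
        assert band.median[0] == pytest.approx(0.0, abs=0.02)
        assert band.upper[0] == pytest.approx(1.6449, abs=0.02)

    def test_level_one_gives_min_max(self):
        vals = np.array([[1.0], [5.0], [3.0]])
        band = prediction_band(vals, level=1.0)
        assert band.lower[0] == 1.0 and band.upper[0] == 5.0

    def test_coverage_for_lognormal_simulator(self):
        rng = np.random.default_rng(8)
        reps = np.exp(rng.normal(0.0, 0.4, (500, 20)))
        band = prediction_band(reps, level=0.90)
        fresh = np.exp(rng.normal(0.0, 0.4, (20_000, 20)))
        inside = (fresh >= band.lower) & (fresh <= band.upper)
        assert inside.mean() == pytest.approx(0.90, abs=0.03)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            prediction_band(np.ones((1, 3)))


class TestBandOverlap:
    def _band(self, lo, hi):
        t = np.arange(4.0)
        return Band(times=t, lower=np.full(4, lo), median=np.full(4, (lo + hi) / 2),
                    upper=np.full(4, hi))

    def test_identical_bands(self):
        b = self._band(0.0, 1.0)
        assert band_overlap(b, b) == 1.0

    def test_disjoint_bands(self):
        assert band_overlap(self._band(0.0, 1.0), self._band(2.0, 3.0)) == 0.0

    def test_nested_half_width(self):
        assert band_overlap(self._band(0.0, 1.0), self._band(0.25, 0.75)) == pytest.approx(0.5)

    def test_mismatched_grids(self):
        b1 = self._band(0.0, 1.0)
        b2 = Band(times=np.arange(5.0), lower=np.zeros(5), median=np.zeros(5),
                  upper=np.ones(5))
        with pytest.raises(ValueError):
            band_overlap(b1, b2)


@pytest.fixture(scope="module")
def result(banded_cohort, params):
    cfg = SimConfig(seed=3, n_replicates=60, standardize_baseline_sds=-1.0)
    return run_banded_study(banded_cohort, params=params, config=cfg)


class TestBandedStudy:
    def test_reference_scenario_difference_is_zero(self, result):
        ref = result.table[result.table.scenario == "target"]
        assert np.all(ref.gv_diff_vs_target == 0.0)

    def test_sign_structure(self, result):
        for _, row in result.table.iterrows():
            if row.scenario.startswith("-"):
                assert row.gv_diff_vs_target >= 0.0
            elif row.scenario.startswith("+"):
                assert row.gv_diff_vs_target <= 0.0

    def test_narrow_within_wide(self, result):
        t = result.table.set_index(["strength_mg", "scenario"])
        for s in t.index.get_level_values(0).unique():
            assert abs(t.loc[(s, "-narrow"), "gv_diff_vs_target"]) <= abs(
                t.loc[(s, "-wide"), "gv_diff_vs_target"]
            )
            assert abs(t.loc[(s, "+narrow"), "gv_diff_vs_target"]) <= abs(
                t.loc[(s, "+wide"), "gv_diff_vs_target"]
            )

    def test_narrow_band_overlaps_more_than_wide(self, result):
        for s in (2.0, 3.5, 5.0):
            assert (
                result.overlap_vs_reference[(s, "-narrow")]
                >= result.overlap_vs_reference[(s, "-wide")]
            )

    def test_replicate_determinism(self, banded_cohort, params):
        cfg = SimConfig(seed=3, n_replicates=20, standardize_baseline_sds=-1.0)
        a = run_banded_study(banded_cohort, params=params, config=cfg)
        b = run_banded_study(banded_cohort, params=params, config=cfg)
        assert a.table.equals(b.table)
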