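"""PK structural model: allometry, Bateman solution, superposition, AUC."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from pegsim.pk import (
    ConcProfile,
    DoseEvent,
    PkParams,
    auc_interval,
    conc_single_dose,
    cumulative_auc,
    individual_params,
    simulate_pk,
    steady_state_auc_tau,
    steady_state_conc,
)

WEEK = 168.0


class TestIndividualParams:
    def test_identity_at_reference(self, params):
        ind = individual_params(params.pk, params.pk.wt_ref, (0, 0, 0))
        assert ind.cl == pytest.approx(params.pk.cl_pop)
        assert ind.v == pytest.approx(params.pk.v_pop)
        assert ind.ka == pytest.approx(params.pk.ka_pop)

    def test_allometric_doubling(self, params):
        ind = individual_params(params.pk, 2 * params.pk.wt_ref)
        assert ind.cl == pytest.approx(params.pk.cl_pop * 2**0.75)
        assert ind.v == pytest.approx(params.pk.v_pop * 2.0)

    def test_lognormal_eta_contract(self, params):
        # sample SD of log CL over 1e5 draws recovers omega_cl within 2 %
        rng = np.random.default_rng(42)
        etas = rng.normal(0.0, params.pk.omega_cl, 100_000)
        log_cl = np.log(
            [individual_params(params.pk, params.pk.wt_ref, (e, 0, 0)).cl for e in etas]
        )
        assert np.std(log_cl) == pytest.approx(params.pk.omega_cl, rel=0.02)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_eta_rejected(self, params, bad):
        with pytest.raises(ValueError):
            individual_params(params.pk, 25.0, (bad, 0, 0))

    def test_nonpositive_weight_rejected(self, params):
        with pytest.raises(ValueError):
            individual_params(params.pk, 0.0)


class TestSingleDose:
    def test_zero_time_and_zero_dose(self, ind):
        assert conc_single_dose(ind, 3.5, 0.0) == 0.0
        t = np.linspace(0, 336, 50)
        assert np.all(conc_single_dose(ind, 0.0, t) == 0.0)

    def test_matches_ode_solution(self, ind):
        # two-state linear ODE integrated adaptively is the independent oracle
        dose = 3.5

        def rhs(t, y):
            a, x = y
            return [-ind.ka * a, ind.ka * a - ind.ke * x]

        sol = solve_ivp(rhs, (0, 336), [ind.f * dose, 0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        t = np.linspace(1.0, 336.0, 64)
        ode_conc = sol.sol(t)[1] / ind.v
        assert np.allclose(conc_single_dose(ind, dose, t), ode_conc, rtol=1e-6)

    def test_ka_equal_ke_limit(self):
        # limiting form is continuous with the general Bateman expression
        base = PkParams(cl_pop=0.025, v_pop=2.5, ka_pop=0.01)
        exact = individual_params(base, 25.0)
        near = individual_params(PkParams(cl_pop=0.025, v_pop=2.5, ka_pop=0.0100001), 25.0)
        t = np.linspace(1, 300, 20)
        assert np.allclose(
            conc_single_dose(exact, 3.5, t), conc_single_dose(near, 3.5, t), rtol=1e-4
        )


class TestSimulatePk:
    def test_empty_dose_list(self, ind):
        grid = np.arange(0.0, 100.0)
        prof = simulate_pk(ind, [], grid)
        assert np.all(prof.conc == 0.0)

    def test_single_dose_reduces_to_bateman(self, ind):
        grid = np.arange(0.0, 337.0)
        prof = simulate_pk(ind, [DoseEvent(0.0, 3.5)], grid)
        assert np.allclose(prof.conc, conc_single_dose(ind, 3.5, grid), rtol=1e-12)

    def test_superposition(self, ind):
        grid = np.arange(0.0, 8 * WEEK + 1)
        a = [DoseEvent(k * WEEK, 3.5) for k in range(0, 8, 2)]
        b = [DoseEvent(k * WEEK, 2.0) for k in range(1, 8, 2)]
        both = simulate_pk(ind, a + b, grid).conc
        split = simulate_pk(ind, a, grid).conc + simulate_pk(ind, b, grid).conc
        assert np.max(np.abs(both - split)) < 1e-9 * both.max()

    def test_dose_proportionality(self, ind):
        grid = np.arange(0.0, 4 * WEEK + 1)
        doses = [DoseEvent(k * WEEK, 3.5) for k in range(4)]
        double = [DoseEvent(k * WEEK, 7.0) for k in range(4)]
        c1 = simulate_pk(ind, doses, grid).conc
        c2 = simulate_pk(ind, double, grid).conc
        assert np.allclose(2 * c1, c2, rtol=1e-12)
        assert auc_interval(ind, double, 0, 4 * WEEK) == pytest.approx(
            2 * auc_interval(ind, doses, 0, 4 * WEEK), rel=1e-12
        )

    def test_week12_trough_matches_steady_state(self, ind):
        # 12 weekly doses accumulate to within 1 % of the analytic SS trough
        doses = [DoseEvent(k * WEEK, 3.5) for k in range(13)]
        grid = np.arange(0.0, 13 * WEEK + 1)
        prof = simulate_pk(ind, doses, grid)
        trough = prof.conc[int(12 * WEEK)]
        ss = steady_state_conc(ind, 3.5, WEEK, WEEK)
        assert trough == pytest.approx(ss, rel=0.01)

    def test_accumulation_nearly_complete_by_week_12(self, ind):
        assert 1.0 - np.exp(-ind.ke * 12 * WEEK) >= 0.95

    def test_terminal_half_life_multi_day(self, ind):
        assert 48.0 <= np.log(2) / ind.ke <= 240.0

    def test_grid_errors(self, ind):
        with pytest.raises(ValueError):
            simulate_pk(ind, [DoseEvent(0.0, 1.0)], np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_pk(ind, [DoseEvent(0.0, 1.0)], np.array([10.0, 20.0]))


class TestAuc:
    def test_zero_doses(self, ind):
        assert auc_interval(ind, [], 0.0, WEEK) == 0.0

    def test_steady_state_interval_equals_f_dose_over_cl(self, ind):
        doses = [DoseEvent(k * WEEK, 3.5) for k in range(30)]
        auc = auc_interval(ind, doses, 25 * WEEK, 26 * WEEK)
        assert auc == pytest.approx(steady_state_auc_tau(ind, 3.5), rel=0.01)

    def test_additivity(self, ind):
        doses = [DoseEvent(k * WEEK, 3.5) for k in range(6)]
        whole = auc_interval(ind, doses, 0.0, 5 * WEEK)
        parts = auc_interval(ind, doses, 0.0, 2 * WEEK) + auc_interval(
            ind, doses, 2 * WEEK, 5 * WEEK
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_against_adaptive_quadrature(self, ind):
        doses = [DoseEvent(k * WEEK, 3.5) for k in range(3)]

        def c(t):
            return sum(conc_single_dose(ind, 3.5, t - d.time) for d in doses)

        oracle, _ = quad(c, 50.0, 400.0, limit=200)
        assert auc_interval(ind, doses, 50.0, 400.0) == pytest.approx(oracle, rel=5e-3)

    def test_bad_interval(self, ind):
        with pytest.raises(ValueError):
            auc_interval(ind, [], 10.0, 10.0)
        with pytest.raises(ValueError):
            auc_interval(ind, [], -5.0, 10.0)


class TestValidation:
    def test_conc_profile_invariants(self):
        with pytest.raises(ValueError):
            ConcProfile(times=np.array([0.0, 0.0, 1.0]), conc=np.zeros(3))
        with pytest.raises(ValueError):
            ConcProfile(times=np.array([0.0, 1.0]), conc=np.array([0.1, -0.5]))

    def test_pk_params_invariants(self):
        with pytest.raises(ValueError):
            PkParams(cl_pop=-1.0, v_pop=2.5, ka_pop=0.03)
        with pytest.raises(ValueError):
            PkParams(cl_pop=0.02, v_pop=2.5, ka_pop=0.03, exp_cl=3.0)

    def test_dose_event_invariants(self):
        with pytest.raises(ValueError):
            DoseEvent(time=-1.0, amount=1.0)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=-1.0)
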