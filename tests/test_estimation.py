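"""FOCE-style estimation: pooled and conditional fits, EB etas, shrinkage."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from pegsim.cohort import generate_ghd_cohort, phase1_design, sparse_pediatric_design
from pegsim.estimation import (
    _laplace_m2ll,
    _PkProblem,
    empirical_bayes,
    fit_pd_sequential,
    fit_pk,
    recovery_report,
)
from pegsim.recovery import _recovery_regimens, recovery_once


def _quiet(params):
    return replace(
        params,
        pk=replace(params.pk, omega_cl=0.0, omega_v=0.0, omega_ka=0.0,
                   sigma_prop=0.0, sigma_add=0.0),
        idr=replace(params.idr, omega_r0=0.0, omega_smax=0.0, sigma_igf=0.0),
        gv=replace(params.gv, omega_gv=0.0, sigma_gv=0.0),
    )


class TestFitPkPooled:
    def test_truth_is_fixed_point_on_noise_free_data(self, params):
        quiet = _quiet(params)
        df = phase1_design(n=1, seed=0, params=quiet)
        fit = fit_pk(df, quiet.pk, method="naive_pooled")
        assert fit.estimates["cl_pop"] == pytest.approx(params.pk.cl_pop, rel=1e-6)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)

    def test_perturbed_init_recovers_noise_free_truth(self, params):
        quiet = _quiet(params)
        df = phase1_design(n=6, seed=1, params=quiet)
        init = replace(quiet.pk, cl_pop=2 * params.pk.cl_pop,
                       v_pop=2 * params.pk.v_pop, ka_pop=2 * params.pk.ka_pop)
        fit = fit_pk(df, init, method="naive_pooled")
        for name, true in [("cl_pop", params.pk.cl_pop), ("v_pop", params.pk.v_pop),
                           ("ka_pop", params.pk.ka_pop)]:
            assert fit.estimates[name] == pytest.approx(true, rel=1e-3)


@pytest.fixture(scope="module")
def foce_fit(params):
    df = phase1_design(n=50, seed=3, params=params)
    init = replace(params.pk, cl_pop=params.pk.cl_pop * 1.3,
                   v_pop=params.pk.v_pop * 0.8, ka_pop=params.pk.ka_pop * 1.3)
    return fit_pk(df, init, method="foce")


class TestFitPkFoce:
    def test_fixed_effect_recovery(self, foce_fit, params):
        for name, true in [("cl_pop", params.pk.cl_pop), ("v_pop", params.pk.v_pop),
                           ("ka_pop", params.pk.ka_pop)]:
            assert abs(foce_fit.estimates[name] - true) / true < 0.15

    def test_omega_recovery(self, foce_fit, params):
        for name, true in [("omega_cl", params.pk.omega_cl),
                           ("omega_v", params.pk.omega_v),
                           ("omega_ka", params.pk.omega_ka)]:
            assert abs(foce_fit.estimates[name] - true) / true < 0.40

    def test_etas_reported_per_subject(self, foce_fit):
        assert set(foce_fit.etas.columns) == {"ID", "eta_cl", "eta_v", "eta_ka"}
        assert len(foce_fit.etas) == 50

    def test_foce_needs_repeated_observations(self, params):
        df = phase1_design(n=2, seed=0, params=params)
        single = df[(df.EVID == 1) | (df.TIME == 24.0)]
        with pytest.raises(ValueError):
            fit_pk(single, params.pk, method="foce")

    def test_foce_reduces_to_pooled_at_zero_omega(self, params):
        # with omegas pinned ~0 the Laplace objective collapses to the pooled
        # -2LL: sum of ln(2 pi var) + squared weighted residuals at eta = 0
        df = phase1_design(n=8, seed=5, params=params)
        problem = _PkProblem(df, params.pk)
        theta = (params.pk.cl_pop, params.pk.v_pop, params.pk.ka_pop)
        tiny = np.array([1e-8, 1e-8, 1e-8])
        sigma = np.array([params.pk.sigma_prop, params.pk.sigma_add])
        m2ll, E = _laplace_m2ll(problem, theta, tiny, sigma, np.zeros((8, 3)))
        F = problem.predict(theta, np.zeros((8, 3)))
        var = (sigma[0] * F) ** 2 + sigma[1] ** 2
        direct = np.where(problem.mask, np.log(2 * np.pi * var)
                          + (problem.y - F) ** 2 / var, 0.0).sum()
        assert m2ll == pytest.approx(direct, rel=1e-6)
        assert np.max(np.abs(E)) < 1e-4


class TestEmpiricalBayes:
    def test_no_observations_prior_mode(self, params):
        df = phase1_design(n=2, seed=0, params=params)
        df = df[df.EVID == 1]  # doses only
        etas = empirical_bayes(df, params.pk)
        assert np.allclose(etas[["eta_cl", "eta_v", "eta_ka"]].to_numpy(), 0.0)

    def test_zero_residual_recovers_true_etas(self, params):
        lownoise = replace(params, pk=replace(params.pk, sigma_prop=1e-5, sigma_add=1e-8))
        df = phase1_design(n=10, seed=7, params=lownoise)
        etas = empirical_bayes(df, lownoise.pk)
        # regenerate the cohort's true etas with the same stream
        from pegsim.seeds import child_rng
        rng = child_rng(7, "phase1")
        true = []
        for _ in range(10):
            rng.normal(65.0, 8.0); rng.uniform(19.0, 45.0)
            true.append([rng.normal(0, params.pk.omega_cl),
                         rng.normal(0, params.pk.omega_v),
                         rng.normal(0, params.pk.omega_ka)])
            for _t in range(15):  # residual draws, interleaved per sample
                rng.normal(0.0, 1e-5); rng.normal(0.0, 1e-8)
        est = etas[["eta_cl", "eta_v", "eta_ka"]].to_numpy()
        assert np.allclose(est, np.array(true), atol=1e-3)

    def test_shrinkage_monotone_in_residual_sd(self, params):
        df = phase1_design(n=10, seed=7, params=params)
        norms = []
        for sp in (0.05, 0.3, 1.0, 4.0):
            pk = replace(params.pk, sigma_prop=sp)
            etas = empirical_bayes(df, pk)[["eta_cl", "eta_v", "eta_ka"]].to_numpy()
            norms.append(np.mean(np.abs(etas)))
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))


class TestSequentialPd:
    def test_noise_free_recovery(self, params):
        # homogeneous noise-free cohort: the deterministic surface returns truth
        quiet = _quiet(params)
        cohort = generate_ghd_cohort(n=12, seed=5, params=quiet)
        for s in cohort:
            s.age, s.sex, s.baseline_igf1_sds = 8.0, "M", -1.27
            s.baseline_gv = params.gv.e0
        regs = _recovery_regimens(cohort, 12)
        ped = sparse_pediatric_design(cohort, months=12, seed=5, params=quiet,
                                      regimens_by_id=regs)
        ph1 = phase1_design(n=4, seed=5, params=quiet)
        pk_fit = fit_pk(ph1, replace(quiet.pk, cl_pop=2 * params.pk.cl_pop),
                        method="naive_pooled")
        init = replace(quiet, gv=replace(quiet.gv, emax_gv=params.gv.emax_gv * 1.3,
                                         auc50=params.gv.auc50 * 0.7, lam=0.05),
                       idr=replace(quiet.idr, smax=params.idr.smax * 1.5))
        fit = fit_pd_sequential(pk_fit, ped, None, init, method="naive_pooled",
                                grid_step_h=1.0)
        assert fit.estimates["gv.e0"] == pytest.approx(params.gv.e0, rel=1e-3)
        assert fit.estimates["gv.emax_gv"] == pytest.approx(params.gv.emax_gv, rel=1e-3)
        assert fit.estimates["gv.auc50"] == pytest.approx(params.gv.auc50, rel=5e-3)
        assert fit.estimates["gv.lam"] == pytest.approx(params.gv.lam, rel=1e-2)
        assert fit.estimates["idr.smax"] == pytest.approx(params.idr.smax, rel=1e-2)

    def test_smax_zero_returns_geometric_mean_baseline(self, params):
        from pegsim.igf1 import sds_to_igf1
        from pegsim.reference import load_igf1_reference

        # data generated without stimulation: the reduced model's baseline
        # estimand is then the cohort geometric-mean baseline
        nostim = replace(params, idr=replace(params.idr, smax=0.0, omega_smax=0.0))
        cohort = generate_ghd_cohort(n=20, seed=9, params=nostim)
        ped = sparse_pediatric_design(cohort, months=6, seed=9, params=nostim)
        ph1 = phase1_design(n=20, seed=9, params=nostim)
        pk_fit = fit_pk(ph1, nostim.pk, method="foce")
        fit = fit_pd_sequential(pk_fit, ped, None, nostim,
                                fixed={"smax": 1e-6, "sc50": params.idr.sc50})
        ref = load_igf1_reference()
        geo = np.exp(np.mean([np.log(sds_to_igf1(s.baseline_igf1_sds, s.age, s.sex, ref))
                              for s in cohort]))
        assert fit.estimates["idr.r0_pop"] == pytest.approx(geo, rel=0.12)

    def test_unconverged_pk_fit_rejected(self, params):
        from pegsim.estimation import FitResult

        bad = FitResult(estimates={}, objective=0.0, converged=False)
        with pytest.raises(ValueError):
            fit_pd_sequential(bad, pd.DataFrame(), None, params)


class TestRecoveryReport:
    def test_exact_and_ten_percent(self):
        from pegsim.estimation import FitResult

        fit = FitResult(estimates={"a": 1.0, "b": 2.2}, objective=0.0, converged=True)
        rep = recovery_report({"a": 1.0, "b": 2.0}, fit)
        assert rep.set_index("param").loc["a", "bias_pct"] == 0.0
        assert rep.set_index("param").loc["b", "bias_pct"] == pytest.approx(10.0)

    def test_missing_parameter_raises(self):
        from pegsim.estimation import FitResult

        fit = FitResult(estimates={"a": 1.0}, objective=0.0, converged=True)
        with pytest.raises(KeyError):
            recovery_report({"zz": 1.0}, fit)
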