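import math

import numpy as np
import pytest
from scipy import optimize, stats

from coxinter import Scenario
from coxinter._kernels import cox_stats, newton_fit
from coxinter.coxcore import (
    BETA_I,
    FitResult,
    PreparedData,
    DesignSpec,
    SolverSettings,
    build_design,
    fit,
    fit_both_parametrizations,
    firth_objective,
    lr_pvalue,
    partial_loglik,
    prepare,
    profile_interval,
    wald_interval,
)
from coxinter.datagen import assemble, eligibility

from .reference_impl import (
    grid_maximize,
    naive_firth_objective,
    naive_loglik,
    naive_score_info,
)

ALL_FREE = np.ones(1, dtype=np.bool_)


def small_dataset(seed, n=40, scenario=None):
    sc = scenario or Scenario(n=n, p_M=0.5, p_T=0.5, p_e=0.5, p_c=0.2,
                              t_end=5.0, OR_MT=1.0, HR_M=2.0, HR_T=0.7,
                              HR_I=0.5, N=1, master_seed=seed)
    return assemble(sc, 0)


class TestTwoSubjectClosedForms:
    def test_loglik_score_info_at_zero(self, two_subject):
        time, d, X = two_subject
        ll, U, I, ok = cox_stats(time, d, X, np.zeros(1), False)
        assert ll == pytest.approx(-math.log(2.0))
        assert U[0] == pytest.approx(0.5)
        assert I[0, 0] == pytest.approx(0.25)
        assert ok

    @pytest.mark.parametrize("b", [-1.0, 0.0, 0.7, 2.5])
    def test_closed_form_curves(self, two_subject, b):
        time, d, X = two_subject
        ll, _, _, _ = cox_stats(time, d, X, np.array([b]), False)
        assert ll == pytest.approx(b - math.log(math.exp(b) + 1.0), abs=1e-12)
        llf, Uf, _, _ = cox_stats(time, d, X, np.array([b]), True)
        assert llf == pytest.approx(1.5 * b - 2.0 * math.log(1.0 + math.exp(b)),
                                    abs=1e-12)
        p = math.exp(b) / (1.0 + math.exp(b))
        assert Uf[0] == pytest.approx(1.5 - 2.0 * p, abs=1e-12)

    def test_monotone_likelihood_mple_diverges(self, two_subject):
        time, d, X = two_subject
        beta, _, _, _, converged, iters, _ = newton_fit(
            time, d, X, False, ALL_FREE, np.zeros(1), 1000, 0.01, 1e-6)
        assert not converged
        assert iters == 1000
        assert beta[0] == pytest.approx(10.0)  # walked maxiter * maxstep

    def test_firth_estimate_is_log3(self, two_subject):
        time, d, X = two_subject
        beta, ll, U, _, converged, _, _ = newton_fit(
            time, d, X, True, ALL_FREE, np.zeros(1), 1000, 0.01, 1e-6)
        assert converged
        assert beta[0] == pytest.approx(math.log(3.0), abs=1e-6)
        assert abs(U[0]) < 1e-6  # stationarity of the modified score


class TestAgainstNaiveImplementation:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_loglik_matches_naive(self, seed):
        ds = small_dataset(seed)
        X = build_design(ds.M, ds.T, "interaction")
        rng = np.random.default_rng(seed)
        beta = rng.normal(scale=0.5, size=3)
        ll, _, _ = partial_loglik(ds, beta)
        assert ll == pytest.approx(naive_loglik(ds.time, ds.event, X, beta),
                                   rel=1e-12)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_score_info_match_naive_and_finite_differences(self, seed):
        ds = small_dataset(seed)
        X = build_design(ds.M, ds.T, "interaction")
        beta = np.array([0.3, -0.2, 0.4])
        _, U, I = partial_loglik(ds, beta)
        U_ref, I_ref = naive_score_info(ds.time, ds.event, X, beta)
        np.testing.assert_allclose(U, U_ref, atol=1e-10)
        np.testing.assert_allclose(I, I_ref, atol=1e-10)
        # numerical gradient of the value matches the analytic score
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            lp, _, _ = partial_loglik(ds, beta + e)
            lm, _, _ = partial_loglik(ds, beta - e)
            assert (lp - lm) / (2 * h) == pytest.approx(U[j], rel=1e-5, abs=1e-6)

    @pytest.mark.parametrize("seed", [6, 7])
    def test_firth_modified_score_matches_numeric_gradient(self, seed):
        ds = small_dataset(seed)
        beta = np.array([0.1, -0.3, 0.2])
        val, U, _ = firth_objective(ds, beta)
        X = build_design(ds.M, ds.T, "interaction")
        assert val == pytest.approx(
            naive_firth_objective(ds.time, ds.event, X, beta), rel=1e-12)
        h = 1e-5
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            vp, _, _ = firth_objective(ds, beta + e)
            vm, _, _ = firth_objective(ds, beta - e)
            assert (vp - vm) / (2 * h) == pytest.approx(U[j], rel=1e-4, abs=1e-6)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tiny_instances_match_grid_search(self, seed):
        """Newton solutions equal grid maximization on <= 8-subject data."""
        rng = np.random.default_rng(seed)
        n = 8
        time = np.sort(rng.exponential(size=n))[::-1].copy()
        d = (rng.random(n) < 0.7).astype(np.int64)
        d[:2] = 1
        x = rng.integers(0, 2, size=n).astype(float)
        x[np.flatnonzero(d)[0]] = 1.0  # ensure both covariate levels among events
        x[np.flatnonzero(d)[1]] = 0.0
        X = x[:, None].copy()
        for use_firth in (False, True):
            obj = (naive_firth_objective if use_firth else naive_loglik)
            b_grid, _ = grid_maximize(
                lambda b: obj(time, d, X, np.array([b])))
            beta, _, _, _, converged, _, _ = newton_fit(
                time, d, X, use_firth, ALL_FREE, np.zeros(1), 5000, 0.05, 1e-9)
            if converged and abs(b_grid) < 4.9:
                assert beta[0] == pytest.approx(b_grid, abs=2e-4)


class TestOracleEquivalence:
    def test_matches_lifelines_on_fixed_datasets(self):
        """MPLE coefficients and Hessian SEs agree with lifelines to 1e-5."""
        import pandas as pd
        from lifelines import CoxPHFitter

        sc = Scenario(n=300, p_M=0.5, p_T=0.5, p_e=0.4, p_c=0.2, t_end=5.0,
                      OR_MT=1.0, HR_M=2.0, HR_T=0.8, HR_I=0.5, N=50,
                      master_seed=2024)
        checked = 0
        for r in range(50):
            ds = assemble(sc, r)
            if not eligibility(ds):
                continue
            res = fit(ds, "interaction", "mple")
            if not res.converged:
                continue
            df = pd.DataFrame({"M": ds.M, "trt": ds.T, "MT": ds.M * ds.T,
                               "time": ds.time, "event": ds.event})
            cph = CoxPHFitter().fit(df, duration_col="time", event_col="event",
                                    fit_options={"precision": 1e-12})
            np.testing.assert_allclose(
                res.coefficients, cph.params_[["M", "trt", "MT"]].to_numpy(),
                atol=1e-5)
            np.testing.assert_allclose(
                np.sqrt(np.diag(res.covariance)),
                cph.standard_errors_[["M", "trt", "MT"]].to_numpy(), atol=1e-5)
            checked += 1
        assert checked >= 45


class TestFitBehaviour:
    def test_time_scale_invariance(self):
        ds = small_dataset(11, n=120)
        res = fit(ds, "interaction", "mple")
        scaled = assemble(
            Scenario(n=120, p_M=0.5, p_T=0.5, p_e=0.5, p_c=0.2, t_end=5.0,
                     OR_MT=1.0, HR_M=2.0, HR_T=0.7, HR_I=0.5, N=1,
                     master_seed=11), 0)
        scaled.time = scaled.time * 3.7
        res2 = fit(scaled, "interaction", "mple")
        np.testing.assert_allclose(res.coefficients, res2.coefficients,
                                   atol=1e-10)

    def test_covariance_properties(self):
        ds = small_dataset(13, n=200)
        res = fit(ds, "interaction", "mple")
        assert res.converged
        cov = res.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_firth_always_finite_in_worst_case_scenario(self):
        """Every Firth fit converges where the standard Cox often cannot."""
        sc = Scenario(n=200, p_M=0.25, p_T=0.5, p_e=0.2, p_c=0.2, t_end=5.0,
                      OR_MT=1.0, HR_M=0.6, HR_T=1.0, HR_I=0.25, N=1000,
                      master_seed=77)
        n_checked = 0
        for r in range(1000):
            ds = assemble(sc, r)
            if not eligibility(ds):
                continue
            res = fit(ds, "interaction", "firth")
            assert res.converged, f"replicate {r} did not converge"
            assert np.all(np.isfinite(res.coefficients))
            n_checked += 1
        assert n_checked > 900


class TestIntervals:
    def test_wald_closed_forms(self):
        res = FitResult(
            coefficients=np.array([0.0]), covariance=np.array([[1.0]]),
            loglik=0.0, converged=True, iterations=3, method="mple",
            parametrization="interaction", score=np.zeros(1))
        lo, hi, p = wald_interval(res, 0, 0.05)
        assert (lo, hi) == (pytest.approx(-1.95996, abs=1e-5),
                            pytest.approx(1.95996, abs=1e-5))
        assert p == pytest.approx(1.0)
        res2 = FitResult(
            coefficients=np.array([1.0986]), covariance=np.array([[0.25]]),
            loglik=0.0, converged=True, iterations=3, method="mple",
            parametrization="interaction", score=np.zeros(1))
        _, _, p2 = wald_interval(res2, 0, 0.05)
        assert p2 == pytest.approx(0.0280, abs=2e-4)

    def test_two_subject_profile_interval_matches_bisection(self, two_subject):
        """PL bounds on the penalized toy equal closed-form 1-D roots."""
        time, d, X = two_subject
        beta, ll, U, I, converged, _, _ = newton_fit(
            time, d, X, True, ALL_FREE, np.zeros(1), 2000, 0.01, 1e-9)
        res = FitResult(coefficients=beta, covariance=np.linalg.inv(I),
                        loglik=ll, converged=True, iterations=1,
                        method="firth", parametrization="interaction",
                        score=U)
        pd_ = PreparedData(time=time, d=d, X=X,
                           design=DesignSpec("interaction"))
        lo, hi, lo_ok, hi_ok = profile_interval(pd_, res, 0, 0.05)
        assert lo_ok and hi_ok

        def lstar(b):
            return 1.5 * b - 2.0 * math.log(1.0 + math.exp(b))

        crit = stats.chi2.ppf(0.95, 1)
        g = lambda b: 2.0 * (lstar(math.log(3.0)) - lstar(b)) - crit
        lo_ref = optimize.bisect(g, -30.0, math.log(3.0), xtol=1e-9)
        hi_ref = optimize.bisect(g, math.log(3.0), 40.0, xtol=1e-9)
        assert lo == pytest.approx(lo_ref, abs=1e-5)
        assert hi == pytest.approx(hi_ref, abs=1e-5)
        assert lo < math.log(3.0) < hi

    def test_profile_bounds_satisfy_chi2_duality(self):
        ds = small_dataset(17, n=150)
        pd_ = prepare(ds, "interaction")
        res = fit(pd_, "interaction", "mple")
        assert res.converged
        lo, hi, lo_ok, hi_ok = profile_interval(pd_, res, BETA_I, 0.05)
        assert lo_ok and hi_ok and lo < res.coefficients[BETA_I] < hi
        crit = stats.chi2.ppf(0.95, 1)
        settings = SolverSettings()
        for bound in (lo, hi):
            free = np.ones(3, dtype=np.bool_)
            free[BETA_I] = False
            b0 = res.coefficients.copy()
            b0[BETA_I] = bound
            _, llb, _, _, conv, _, _ = newton_fit(
                pd_.time, pd_.d, pd_.X, False, free, b0,
                settings.maxiter, settings.maxstep, settings.tol)
            assert conv
            assert 2.0 * (res.loglik - llb) == pytest.approx(crit, abs=1e-4)

    def test_profile_interval_near_wald_for_large_samples(self):
        """With many events the likelihood is near-quadratic, so PL ~ Wald."""
        sc = Scenario(n=4000, p_M=0.5, p_T=0.5, p_e=0.5, p_c=0.2, t_end=5.0,
                      OR_MT=1.0, HR_M=1.5, HR_T=0.9, HR_I=0.7, N=1,
                      master_seed=21)
        ds = assemble(sc, 0)
        pd_ = prepare(ds, "interaction")
        res = fit(pd_, "interaction", "mple")
        w_lo, w_hi, _ = wald_interval(res, BETA_I, 0.05)
        p_lo, p_hi, lo_ok, hi_ok = profile_interval(pd_, res, BETA_I, 0.05)
        assert lo_ok and hi_ok
        width = w_hi - w_lo
        assert abs(p_lo - w_lo) < 0.03 * width
        assert abs(p_hi - w_hi) < 0.03 * width

    def test_lr_pvalue_and_nonconverged_flagging(self, two_subject):
        ds = small_dataset(19, n=150)
        pd_ = prepare(ds, "interaction")
        res = fit(pd_, "interaction", "mple")
        p, ok = lr_pvalue(pd_, res, BETA_I)
        assert ok and 0.0 <= p <= 1.0
        bad = FitResult(coefficients=np.full(3, np.nan),
                        covariance=np.full((3, 3), np.nan), loglik=np.nan,
                        converged=False, iterations=1000, method="mple",
                        parametrization="interaction", score=np.full(3, np.nan))
        assert np.isnan(wald_interval(bad, BETA_I)[0])
        assert profile_interval(pd_, bad, BETA_I)[2] is False


class TestBothParametrizations:
    def test_mple_reparametrization_identity(self):
        ds = small_dataset(23, n=200)
        out = fit_both_parametrizations(ds, "mple", pl=False)
        fi, fs = out["interaction"], out["subgroup"]
        assert fi.converged and fs.converged
        # same model space: equal maximized likelihoods
        assert fi.loglik == pytest.approx(fs.loglik, abs=1e-8)
        # gamma_high - gamma_low = beta_I
        diff = fs.coefficients[2] - fs.coefficients[1]
        assert diff == pytest.approx(fi.coefficients[2], abs=1e-6)
        # and gamma_low = beta_T
        assert fs.coefficients[1] == pytest.approx(fi.coefficients[1], abs=1e-6)

    def test_firth_parametrizations_reported_not_asserted(self):
        """The Firth penalty is not reparametrization-invariant in general;
        for this unit-determinant recoding the implied HRs agree closely."""
        ds = small_dataset(29, n=200)
        out = fit_both_parametrizations(ds, "firth", pl=False)
        fi, fs = out["interaction"], out["subgroup"]
        assert fi.converged and fs.converged
        diff = fs.coefficients[2] - fs.coefficients[1]
        discrepancy = abs(diff - fi.coefficients[2])
        assert discrepancy < 1e-3

    def test_zero_event_dataset_rejected(self):
        from coxinter.datagen import SurvivalDataset

        ds = SurvivalDataset(M=np.array([0, 1]), T=np.array([0, 1]),
                             time=np.array([1.0, 2.0]),
                             event=np.array([0, 0]))
        with pytest.raises(ValueError):
            prepare(ds, "interaction")
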