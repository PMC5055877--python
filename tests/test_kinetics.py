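"""Closed-form kinetics, stationary-phase estimators and parameter fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fermopt import (
    ConvergenceError,
    KineticParams,
    KineticsError,
    TimeCourse,
    beta_from_stationary,
    eta_from_stationary,
    fit_kinetics,
    fit_lilp,
    fit_limlp,
    fit_logistic,
    goodness,
    lilp_product,
    limlp_substrate,
    logistic_biomass,
    stationary_slope,
)
from fermopt.kinetics import (
    LuedekingPiretSubstrate,
    log_growth_term,
    read_timecourse,
    write_timecourse,
)


def ode_solution(p: KineticParams, t_eval):
    """Independent oracle: adaptive integration of the rate equations
    dX/dt = mu X (1 - X/Xm), -dS/dt = gamma dX/dt + eta X,
    dP/dt = alpha dX/dt + beta X."""

    def rhs(_t, y):
        x = y[0]
        dx = p.mu_max * x * (1 - x / p.xm)
        return [dx, -(p.gamma * dx + p.eta * x), p.alpha * dx + p.beta * x]

    sol = solve_ivp(rhs, (0.0, float(np.max(t_eval))), [p.x0, p.s0, p.p0],
                    t_eval=np.asarray(t_eval, float), rtol=1e-10, atol=1e-12)
    assert sol.success
    return sol.y


def random_params(rng: np.random.Generator) -> KineticParams:
    x0 = rng.uniform(1e-3, 0.05)
    return KineticParams(
        mu_max=rng.uniform(0.2, 1.5),
        x0=x0,
        xm=x0 + rng.uniform(0.05, 1.0),
        gamma=rng.uniform(0, 10),
        eta=rng.uniform(0, 5),
        alpha=rng.uniform(0, 150),
        beta=rng.uniform(0, 10),
        s0=rng.uniform(10, 30),
        p0=rng.uniform(0, 2),
    )


@pytest.fixture(scope="module")
def xc_params(fixtures=None):
    from fermopt import study_fixtures

    return study_fixtures()["kinetics"]["xcampestris"]


class TestClosedForms:
    def test_initial_values(self, xc_params):
        p = xc_params
        assert logistic_biomass(0.0, p) == pytest.approx(p.x0, rel=1e-12)
        assert limlp_substrate(0.0, p) == pytest.approx(p.s0, rel=1e-12)
        assert lilp_product(0.0, p) == pytest.approx(p.p0, abs=1e-12)

    def test_biomass_saturates_at_xm(self, xc_params):
        t_large = 50.0 / xc_params.mu_max
        assert logistic_biomass(t_large, xc_params) == pytest.approx(xc_params.xm, rel=1e-10)

    def test_biomass_day11_matches_ode_oracle(self, xc_params):
        x11 = logistic_biomass(11.0, xc_params)
        x_ode = ode_solution(xc_params, [11.0])[0][-1]
        assert x11 == pytest.approx(x_ode, rel=1e-8)
        assert x11 == pytest.approx(0.2232, abs=5e-5)  # 4 d.p. reference value

    def test_substrate_decreases_and_matches_ode(self, xc_params):
        s2 = limlp_substrate(2.0, xc_params)
        s_ode = ode_solution(xc_params, [2.0])[1][-1]
        assert s2 == pytest.approx(s_ode, rel=1e-6)
        assert s2 < xc_params.s0

    def test_zero_coefficients_freeze_series(self, xc_params):
        p = KineticParams(mu_max=xc_params.mu_max, x0=xc_params.x0, xm=xc_params.xm,
                          gamma=0.0, eta=0.0, alpha=0.0, beta=0.0, s0=20.0, p0=1.5)
        t = np.linspace(0, 12, 25)
        assert np.allclose(limlp_substrate(t, p), 20.0, rtol=1e-12)
        assert np.allclose(lilp_product(t, p), 1.5, rtol=1e-12)

    def test_product_reproduces_reported_harvest_zones(self):
        from fermopt import study_fixtures

        fx = study_fixtures()
        for org, params in fx["kinetics"].items():
            expected = fx["reported_max_zones"]["model_fitted"][org]
            assert lilp_product(11.0, params) == pytest.approx(expected, abs=0.05)

    def test_product_asymptotic_slope_is_beta_xm(self, xc_params):
        # for mu*t >> 1 the product grows linearly at rate beta * Xm
        p = xc_params
        t = 40.0 / p.mu_max
        slope = (lilp_product(t + 0.5, p) - lilp_product(t - 0.5, p)) / 1.0
        assert slope == pytest.approx(p.beta * p.xm, rel=1e-6)

    def test_substrate_exhaustion_warns(self, xc_params):
        with pytest.warns(UserWarning, match="exhaustion"):
            s = limlp_substrate(200.0, xc_params)
        assert s < 0

    def test_analytic_matches_ode_over_random_params(self):
        rng = np.random.default_rng(77)
        t = np.linspace(0.0, 15.0, 16)
        for _ in range(20):
            p = random_params(rng)
            x_ode, s_ode, p_ode = ode_solution(p, t[1:])
            scale_s = max(abs(p.s0), 1.0)
            assert np.allclose(logistic_biomass(t[1:], p), x_ode, rtol=1e-6)
            assert np.max(np.abs(limlp_substrate(t[1:], p, warn_negative=False) - s_ode)) < 1e-6 * scale_s
            assert np.allclose(lilp_product(t[1:], p), p_ode, rtol=1e-6, atol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        mu=st.floats(0.05, 3.0),
        x0_frac=st.floats(1e-4, 0.99),
        xm=st.floats(0.01, 10.0),
        t=st.floats(0.0, 100.0),
    )
    def test_log_growth_term_nonnegative_and_biomass_monotone(self, mu, x0_frac, xm, t):
        p = KineticParams(mu_max=mu, x0=x0_frac * xm, xm=xm)
        assert log_growth_term(t, p) >= -1e-12
        assert logistic_biomass(t, p) <= xm * (1 + 1e-12)
        assert logistic_biomass(t + 0.1, p) >= logistic_biomass(t, p) - 1e-15


class TestStationaryPhase:
    def test_eta_and_beta_division(self):
        assert eta_from_stationary(0.0, 0.226) == 0.0
        assert eta_from_stationary(-0.58, 0.226) == pytest.approx(2.566371681, abs=1e-9)
        assert eta_from_stationary(-1.0, 0.5) == pytest.approx(2.0)
        assert beta_from_stationary(0.0, 0.226) == 0.0
        assert beta_from_stationary(2.0, 0.226) == pytest.approx(8.8496, abs=5e-5)
        assert beta_from_stationary(1.0, 0.226) == pytest.approx(4.4248, abs=5e-5)

    def test_nonpositive_xmax_rejected(self):
        with pytest.raises(KineticsError):
            eta_from_stationary(-0.5, 0.0)
        with pytest.raises(KineticsError):
            beta_from_stationary(0.5, -1.0)

    def test_slope_of_linear_series(self):
        t = np.arange(0.0, 12.0)
        tc = TimeCourse(times=t, biomass=np.full(12, 0.2), substrate=30 - 0.5 * t,
                        product=np.full(12, 3.0))
        assert stationary_slope(tc, "S", (5, 11)) == pytest.approx(-0.5, rel=1e-12)
        assert stationary_slope(tc, "P", (5, 11)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_matches_closed_form(self):
        rng = np.random.default_rng(4)
        t = np.arange(0.0, 12.0)
        s = 25 - 0.58 * t + rng.normal(0, 0.1, t.size)
        tc = TimeCourse(times=t, biomass=np.full(12, 0.2), substrate=s)
        window = (5.0, 11.0)
        mask = (t >= 5) & (t <= 11)
        tw, sw = t[mask], s[mask]
        slope_formula = np.sum((tw - tw.mean()) * (sw - sw.mean())) / np.sum((tw - tw.mean()) ** 2)
        assert stationary_slope(tc, "S", window) == pytest.approx(slope_formula, rel=1e-12)

    def test_insufficient_points_rejected(self):
        tc = TimeCourse(times=np.arange(4.0), biomass=np.ones(4), substrate=np.ones(4))
        with pytest.raises(KineticsError, match="need >= 2"):
            stationary_slope(tc, "S", (10, 11))


class TestLogisticFit:
    def test_noise_free_recovery(self, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, xc_params))
        mu, x0, xm, r2 = fit_logistic(tc)
        assert mu == pytest.approx(xc_params.mu_max, rel=1e-6)
        assert x0 == pytest.approx(xc_params.x0, rel=1e-6)
        assert xm == pytest.approx(xc_params.xm, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_mu_max_recovery_over_replicates(self, xc_params):
        t = np.arange(0.0, 13.0)
        truth = logistic_biomass(t, xc_params)
        rng = np.random.default_rng(99)
        mus = []
        for _ in range(50):
            x = np.clip(truth + rng.normal(0, 0.005, t.size), 1e-4, None)
            mu, *_ = fit_logistic(TimeCourse(times=t, biomass=x))
            mus.append(mu)
        median_err = abs(np.median(mus) - xc_params.mu_max) / xc_params.mu_max
        assert median_err < 0.10

    def test_constant_series_fails_to_converge(self):
        tc = TimeCourse(times=np.arange(6.0), biomass=np.full(6, 0.2))
        with pytest.raises(ConvergenceError):
            fit_logistic(tc)

    def test_too_few_points_rejected(self):
        tc = TimeCourse(times=np.arange(3.0), biomass=np.array([0.01, 0.05, 0.1]))
        with pytest.raises(KineticsError, match=">= 4"):
            fit_logistic(tc)


class TestConditionalFits:
    def test_lilp_noise_free_recovery(self, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, xc_params),
                        product=lilp_product(t, xc_params))
        alpha, beta, r2 = fit_lilp(tc, xc_params)
        assert alpha == pytest.approx(xc_params.alpha, rel=1e-6)
        assert beta == pytest.approx(xc_params.beta, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_lilp_alpha_zero_truth(self, xc_params):
        rng = np.random.default_rng(21)
        truth = KineticParams(mu_max=xc_params.mu_max, x0=xc_params.x0, xm=xc_params.xm,
                              alpha=0.0, beta=5.0, p0=0.0)
        t = np.arange(0.0, 13.0)
        p_obs = lilp_product(t, truth) + rng.normal(0, 0.05, t.size)
        p_obs[0] = 0.0
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, truth), product=p_obs)
        alpha, beta, _ = fit_lilp(tc, truth)
        assert alpha < 1.0  # within noise of zero on the mm/g-biomass scale
        assert beta == pytest.approx(5.0, rel=0.05)

    def test_limlp_noise_free_recovery(self, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, xc_params),
                        substrate=limlp_substrate(t, xc_params))
        gamma, eta, r2 = fit_limlp(tc, xc_params)
        assert gamma == pytest.approx(xc_params.gamma, rel=1e-6)
        assert eta == pytest.approx(xc_params.eta, rel=1e-6)

    def test_limlp_constant_substrate_gives_zero_coefficients(self, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, xc_params),
                        substrate=np.full(t.size, 20.0))
        gamma, eta, _ = fit_limlp(tc, xc_params)
        assert gamma == pytest.approx(0.0, abs=1e-10)
        assert eta == pytest.approx(0.0, abs=1e-10)

    def test_limlp_optimum_beats_random_probes(self, xc_params):
        rng = np.random.default_rng(8)
        t = np.arange(0.0, 13.0)
        s_obs = limlp_substrate(t, xc_params) + rng.normal(0, 0.2, t.size)
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, xc_params), substrate=s_obs)
        est = LuedekingPiretSubstrate(growth=xc_params).fit(t, s_obs)
        ss_opt = float(np.sum((s_obs - est.predict(t)) ** 2))
        for _ in range(100):
            probe = KineticParams(mu_max=xc_params.mu_max, x0=xc_params.x0, xm=xc_params.xm,
                                  gamma=rng.uniform(0, 10), eta=rng.uniform(0, 5),
                                  s0=est.intercept_)
            ss = float(np.sum((s_obs - limlp_substrate(t, probe, warn_negative=False)) ** 2))
            assert ss_opt <= ss + 1e-9

    def test_invalid_growth_params_rejected(self):
        with pytest.raises(KineticsError, match="x0 < xm"):
            KineticParams(mu_max=0.7, x0=0.3, xm=0.2)


class TestCombinedFit:
    def test_sequential_pipeline_recovers_everything(self, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(
            times=t,
            biomass=logistic_biomass(t, xc_params),
            substrate=limlp_substrate(t, xc_params),
            product=lilp_product(t, xc_params),
        )
        fit = fit_kinetics(tc)
        p = fit.params
        for name in ("mu_max", "x0", "xm", "gamma", "eta", "alpha", "beta"):
            assert getattr(p, name) == pytest.approx(getattr(xc_params, name), rel=1e-6), name
        assert fit.r_squared_product == pytest.approx(1.0, abs=1e-10)

    def test_joint_refinement_stays_at_noise_free_optimum(self, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(
            times=t,
            biomass=logistic_biomass(t, xc_params),
            substrate=limlp_substrate(t, xc_params),
            product=lilp_product(t, xc_params),
        )
        fit = fit_kinetics(tc, joint=True)
        assert fit.params.mu_max == pytest.approx(xc_params.mu_max, rel=1e-4)
        assert fit.params.alpha == pytest.approx(xc_params.alpha, rel=1e-4)


class TestGoodnessAndIO:
    def test_goodness_trivial_cases(self):
        obs = np.array([2.0, 4.0, 6.0, 8.0])
        r2, rmse, aad = goodness(obs, obs)
        assert (r2, rmse, aad) == (1.0, 0.0, 0.0)
        r2, _, _ = goodness(obs, np.full(4, obs.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_goodness_matches_direct_formulas(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(10, 30, 20)
        pred = obs + rng.normal(0, 1, 20)
        r2, rmse, aad = goodness(obs, pred)
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
        assert rmse == pytest.approx(np.sqrt(ss_res / 20), rel=1e-12)
        assert aad == pytest.approx(100 / 20 * np.sum(np.abs((obs - pred) / obs)), rel=1e-12)

    def test_timecourse_validation(self):
        with pytest.raises(KineticsError, match="strictly increasing"):
            TimeCourse(times=np.array([0.0, 2.0, 1.0]), biomass=np.ones(3))
        with pytest.raises(KineticsError, match="length"):
            TimeCourse(times=np.arange(3.0), biomass=np.ones(3), product=np.ones(4))

    def test_csv_roundtrip(self, tmp_path, xc_params):
        t = np.arange(0.0, 13.0)
        tc = TimeCourse(times=t, biomass=logistic_biomass(t, xc_params),
                        substrate=limlp_substrate(t, xc_params),
                        product=lilp_product(t, xc_params))
        path = tmp_path / "tc.csv"
        write_timecourse(tc, path)
        back = read_timecourse(path)
        assert np.allclose(back.biomass, tc.biomass)
        assert np.allclose(back.substrate, tc.substrate)
        assert np.allclose(back.product, tc.product)
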