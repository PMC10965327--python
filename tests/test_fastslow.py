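import numpy as np
import pytest

from transientad import (DimlessParams, dimensionless_rhs, fast_equilibrium,
                         fast_rhs, fast_stability, integrate,
                         piecewise_transient, slow_flow, slow_manifold_point,
                         stage_times)


class TestFastRhs:
    def test_y_rate_is_exactly_zero(self, dimless_params):
        rate = fast_rhs([1.0, 2.0, 3.0, 40.0], dimless_params)
        assert rate[3] == 0.0

    def test_fast_origin(self, dimless_params):
        rate = fast_rhs([0, 0, 0, 25.0], dimless_params)
        np.testing.assert_allclose(rate, [dimless_params.alpha, 0, 0, 0])

    def test_is_eps_to_zero_limit_of_full_model(self, dimless_params):
        # term-by-term the fast subsystem is the full rhs with eps -> 0
        tiny = DimlessParams.default(alpha=6.0, eps=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = rng.uniform(0, 50, size=4)
            np.testing.assert_allclose(fast_rhs(state, dimless_params),
                                       dimensionless_rhs(state, tiny),
                                       atol=1e-9)


class TestFastEquilibrium:
    def test_closed_forms(self, dimless_params):
        u, v, x = fast_equilibrium(dimless_params, y=30.0)
        assert u == pytest.approx(0.1 / 0.9, rel=1e-12)
        assert x == pytest.approx(6 / 0.0336, rel=1e-12)
        assert v == pytest.approx(6 / (0.336 * 30 - 6), rel=1e-12)

    def test_u_star_independent_of_y(self, dimless_params):
        assert (fast_equilibrium(dimless_params, 30)[0]
                == fast_equilibrium(dimless_params, 90)[0])

    def test_is_fixed_point(self, dimless_params):
        u, v, x = fast_equilibrium(dimless_params, 30.0)
        rate = fast_rhs([u, v, x, 30.0], dimless_params)
        assert np.abs(rate[:3]).max() < 1e-12

    def test_error_below_washout_threshold(self, dimless_params):
        with pytest.raises(ValueError, match="beta"):
            fast_equilibrium(dimless_params, y=1.0)


class TestFastStability:
    def test_stable_at_reference_point(self, dimless_params):
        eig, stable = fast_stability(dimless_params, y=30.0)
        assert stable and np.all(eig.real < 0)

    def test_eigenvalues_sorted_by_real_part(self, dimless_params):
        eig, _ = fast_stability(dimless_params, y=30.0)
        assert np.all(np.diff(eig.real) <= 1e-12)

    def test_jacobian_step_refinement(self, dimless_params):
        e1, _ = fast_stability(dimless_params, y=30.0, step_scale=1e-6)
        e2, _ = fast_stability(dimless_params, y=30.0, step_scale=5e-7)
        assert np.max(np.abs(e1 - e2) / np.abs(e1)) < 1e-6

    def test_long_fast_run_converges_to_equilibrium(self, dimless_params):
        eq = np.array(fast_equilibrium(dimless_params, 30.0))
        ts = integrate(fast_rhs, [0.1, 0.1, 0.1, 30.0], t_max=200, dt=0.01,
                       params=dimless_params)
        assert np.abs(ts.states[-1][:3] - eq).max() < 1e-5

    @pytest.mark.parametrize("alpha", [0.001, 1.0, 6.0])
    def test_stable_across_parameter_box(self, alpha):
        p = DimlessParams.default(alpha=alpha)
        for y in np.linspace(alpha / p.beta + 0.1, 100.0, 6):
            _, stable = fast_stability(p, y)
            assert stable


class TestSlowDynamics:
    def test_manifold_residual_and_closed_form(self, dimless_params):
        u, v, x = slow_manifold_point(30.0, dimless_params)
        rate = fast_rhs([u, v, x, 30.0], dimless_params)
        assert np.abs(rate[:3]).max() < 1e-10
        ue, ve, xe = fast_equilibrium(dimless_params, 30.0)
        np.testing.assert_allclose([u, v, x], [ue, ve, xe], rtol=1e-8)

    def test_slow_flow_fixed_point(self, dimless_params):
        p = dimless_params
        v_eq = (1 + p.sigma2) / (p.omega - 1 - p.sigma2)
        y_eq = p.alpha * (1 + 1 / v_eq) / p.beta
        sf = slow_flow(y_eq, p, s_max=1.0, ds=0.01)
        assert np.abs(sf.column("y") - y_eq).max() < 1e-6

    def test_slow_flow_y_stays_positive(self, dimless_params):
        sf = slow_flow(30.0, dimless_params, s_max=2.0, ds=0.01)
        assert np.all(sf.column("y") > 0)

    def test_full_model_tracks_slow_flow_at_small_eps(self):
        # Fenichel limit: y of the full model at eps=1e-3 follows the
        # constrained slow flow after the initial layer
        p = DimlessParams(eps=1e-3, alpha=6, beta=0.336, sigma1=0.1,
                          sigma2=0.0667, omega=4.27)
        full = integrate(dimensionless_rhs, [0.1, 0.1, 0.1, 30.0],
                         t_max=100.0, dt=0.01, params=p)
        sf = slow_flow(30.0, p, s_max=0.1, ds=0.001)
        for s_chk in (0.05, 0.1):
            y_full = full.column("y")[int(round(s_chk / p.eps / 0.01))]
            y_slow = sf.column("y")[int(round(s_chk / 0.001))]
            assert abs(y_full - y_slow) / y_slow < 0.01


class TestStagedTransient:
    def test_stage_time_closed_forms(self, dimless_params):
        st = stage_times([0, 0, 0.05, 30.0], dimless_params, eps_tol=0.05)
        assert st.u_tol == pytest.approx(19.0)
        assert st.tau1 == pytest.approx(19 / 6, rel=1e-12)
        assert st.tau2 == pytest.approx(np.log(6 / 0.0168) + 19 / 6,
                                        rel=1e-9)
        assert st.tau2 == pytest.approx(9.045, abs=2e-3)

    def test_tau1_zero_at_boundary(self, dimless_params):
        st = stage_times([19.0, 0, 0.05, 30.0], dimless_params, 0.05)
        assert st.tau1 == 0.0

    def test_tau1_scales_inversely_with_alpha(self):
        t1 = stage_times([0, 0, 0.05, 30.0], DimlessParams.default(alpha=3)).tau1
        t2 = stage_times([0, 0, 0.05, 30.0], DimlessParams.default(alpha=6)).tau1
        assert t1 == pytest.approx(2 * t2, rel=1e-12)

    def test_tau2_needs_bacteria(self, dimless_params):
        with pytest.raises(ValueError, match="x0"):
            stage_times([0, 0, 0.0, 30.0], dimless_params)

    def test_degenerate_flag_when_alpha_small(self):
        p = DimlessParams.default(alpha=0.001)
        st = stage_times([0, 0, 0.05, 30.0], p)
        assert st.degenerate and st.tau2 <= st.tau1

    def test_stage1_is_linear_inflow(self, dimless_params):
        init = np.array([0.0, 0.0, 0.05, 30.0])
        ts, st = piecewise_transient(init, dimless_params, 0.05,
                                     t_max=12, dt=0.01)
        i1 = int(round(st.tau1 / 0.01))
        u = ts.column("u")[:i1 + 1]
        np.testing.assert_allclose(
            u, init[0] + dimless_params.alpha * ts.times[:i1 + 1],
            atol=1e-10)
        for col in ("v", "x", "y"):
            assert np.all(ts.column(col)[:i1 + 1]
                          == ts.column(col)[0])

    def test_stage2_exponential_growth(self, dimless_params):
        init = np.array([0.0, 0.0, 0.05, 30.0])
        ts, st = piecewise_transient(init, dimless_params, 0.05,
                                     t_max=12, dt=0.01)
        i1 = int(round(st.tau1 / 0.01))
        i2 = int(round(st.tau2 / 0.01))
        x = ts.column("x")
        closed = x[i1] * np.exp((1 - dimless_params.sigma1)
                                * (ts.times[i1:i2 + 1] - ts.times[i1]))
        assert np.abs(x[i1:i2 + 1] - closed).max() / closed.max() < 1e-6

    def test_tracks_full_fast_subsystem_qualitatively(self, dimless_params):
        # single u-maximum, located between tau1 and 1.5 tau2
        init = np.array([0.0, 0.0, 0.05, 30.0])
        full = integrate(fast_rhs, init, t_max=20, dt=0.01,
                         params=dimless_params)
        st = stage_times(init, dimless_params, 0.05)
        t_umax = full.times[np.argmax(full.column("u"))]
        assert st.tau1 <= t_umax <= 1.5 * st.tau2
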