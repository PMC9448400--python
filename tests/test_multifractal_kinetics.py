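"""Fokker-Planck transition density, hydrodynamic diagnostics, the
particle-level oracle, and the two-timescale fractal fit."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

import micelkin as mk
from micelkin.multifractal_kinetics import (
    DegenerateDensityError,
    solve_eta_for_early_fraction,
)
from micelkin.synthetic_data import default_times


class TestDensityAndMoments:
    def test_variance_saturates_at_D_over_eta(self, ou_params):
        _, var = mk.ou_moments(1e6, ou_params)
        assert var == pytest.approx(ou_params.D / ou_params.eta, rel=1e-12)

    def test_mean_decays_exponentially(self):
        p = mk.OUParameters(D=1.0, eta=1.0, x0=1.0)
        mean, _ = mk.ou_moments(1.0, p)
        assert mean == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_t0_moments_are_initial_condition(self, ou_params):
        assert mk.ou_moments(0.0, ou_params) == (ou_params.x0, 0.0)

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_density_integrates_to_one(self, ou_params, t):
        _, var = mk.ou_moments(t, ou_params)
        lim = 10.0 * np.sqrt(var)
        total, _ = quad(lambda x: mk.ou_density(x, t, ou_params),
                        ou_params.x0 - lim, ou_params.x0 + lim)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_quadrature_moments_match_closed_form(self, ou_params):
        t = 1.0
        mean, var = mk.ou_moments(t, ou_params)
        lim = 12.0 * np.sqrt(var)
        m1, _ = quad(lambda x: x * mk.ou_density(x, t, ou_params), -lim, lim)
        m2, _ = quad(lambda x: (x - mean) ** 2 * mk.ou_density(x, t, ou_params),
                     -lim, lim)
        assert m1 == pytest.approx(mean, abs=1e-8)
        assert m2 == pytest.approx(var, abs=1e-8)

    def test_density_degenerate_at_t0(self, ou_params):
        with pytest.raises(DegenerateDensityError):
            mk.ou_density(0.0, 0.0, ou_params)


class TestFokkerPlanckResidual:
    def test_second_order_convergence(self, ou_params):
        """Halving both mesh spacings divides the residual by ~4."""
        x1, t1 = np.linspace(-6, 6, 201), np.linspace(0.5, 1.5, 101)
        x2, t2 = np.linspace(-6, 6, 401), np.linspace(0.5, 1.5, 201)
        r1 = mk.fokker_planck_residual(ou_params, x1, t1)
        r2 = mk.fokker_planck_residual(ou_params, x2, t2)
        assert r1 / r2 == pytest.approx(4.0, abs=0.3)

    def test_wrong_relaxation_rate_leaves_residual_large(self, ou_params):
        """Negative control: density evolved with eta but tested at 2 eta."""
        wrong = mk.OUParameters(D=ou_params.D, eta=2.0 * ou_params.eta,
                                x0=ou_params.x0)
        x, t = np.linspace(-6, 6, 201), np.linspace(0.5, 1.5, 101)
        resid = mk.fokker_planck_residual(
            wrong, x, t, density=lambda xx, tt, _p: mk.ou_density(xx, tt, ou_params))
        assert resid > 0.01

    def test_advection_dominated_narrow_gaussian(self):
        """Near-zero D (narrow transported Gaussian): the residual is still
        pure discretization error, vanishing at second order."""
        p = mk.OUParameters(D=1e-4, eta=0.5, x0=1.0)
        r1 = mk.fokker_planck_residual(p, np.linspace(0.4, 0.9, 401),
                                       np.linspace(0.8, 1.2, 201))
        r2 = mk.fokker_planck_residual(p, np.linspace(0.4, 0.9, 801),
                                       np.linspace(0.8, 1.2, 401))
        assert r1 / r2 == pytest.approx(4.0, abs=0.4)
        # scale: the density itself peaks around 35, so this is tiny
        assert r2 < 1.0

    def test_coarse_mesh_rejected(self, ou_params):
        with pytest.raises(ValueError, match="coarse"):
            mk.fokker_planck_residual(ou_params, np.array([0.0, 1.0]),
                                      np.array([1.0, 2.0, 3.0]))


class TestHydrodynamics:
    def test_uniform_density_gives_zero_fields(self):
        x = np.linspace(-1, 1, 101)
        f = mk.hydrodynamic_diagnostics(x, np.ones_like(x), mk.ScaleParameters())
        np.testing.assert_allclose(f.V_F, 0.0, atol=1e-12)
        np.testing.assert_allclose(f.Q, 0.0, atol=1e-12)

    def test_unit_gaussian_fractal_velocity_is_minus_x(self):
        sp = mk.ScaleParameters(lam=1.0, dt_res=1.0, f_alpha=2.0)  # amplitude 1
        x = np.linspace(-3, 3, 601)
        rho = np.exp(-x**2 / 2) / np.sqrt(2 * np.pi)
        f = mk.hydrodynamic_diagnostics(x, rho, sp)
        np.testing.assert_allclose(f.V_F, -x, atol=1e-3)

    def test_unit_gaussian_potential_matches_analytic_form(self):
        # for rho ~ exp(-x^2/2) and amplitude a: Q = a^2 (1 - x^2/2)
        sp = mk.ScaleParameters(lam=1.0, dt_res=1.0, f_alpha=2.0)
        x = np.linspace(-3, 3, 601)
        rho = np.exp(-x**2 / 2) / np.sqrt(2 * np.pi)
        f = mk.hydrodynamic_diagnostics(x, rho, sp)
        # one-sided stencils degrade the nested derivative at the ends;
        # compare away from the boundary
        np.testing.assert_allclose(f.Q[5:-5], (1.0 - x**2 / 2.0)[5:-5],
                                   atol=1e-3)

    def test_nonpositive_density_rejected(self):
        x = np.linspace(-1, 1, 11)
        with pytest.raises(ValueError):
            mk.hydrodynamic_diagnostics(x, np.zeros_like(x), mk.ScaleParameters())


class TestScaleTransition:
    def test_unit_resolution_halves_D(self):
        sp = mk.ScaleParameters(lam=1.0, dt_res=1.0, f_alpha=1.3)
        assert mk.lambda_from_D(3.0, sp) == pytest.approx(1.5)

    def test_monofractal_exponent_vanishes(self):
        # f(alpha) = 2 makes the dt exponent zero: lambda = D/2 for any dt
        for dt in (0.1, 1.0, 7.0):
            sp = mk.ScaleParameters(lam=1.0, dt_res=dt, f_alpha=2.0)
            assert mk.lambda_from_D(3.0, sp) == pytest.approx(1.5)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sp = mk.ScaleParameters(lam=1.0, dt_res=rng.uniform(0.1, 5.0),
                                    f_alpha=rng.uniform(0.5, 3.0))
            d = rng.uniform(0.1, 10.0)
            assert mk.D_from_lambda(mk.lambda_from_D(d, sp), sp) == pytest.approx(
                d, rel=1e-14)


class TestEnsembleOracle:
    def test_deterministic_limit_follows_exponential_decay(self):
        p = mk.OUParameters(D=0.0, eta=1.0, x0=1.0)
        t = np.array([0.5, 1.0, 2.0])
        ens = mk.simulate_ou_ensemble(p, 10, t, step=1e-4, seed=0)
        np.testing.assert_allclose(
            ens.positions, np.broadcast_to(np.exp(-t), (10, 3)), rtol=1e-3)

    def test_moments_within_three_standard_errors(self):
        p = mk.OUParameters(D=1.0, eta=1.0, x0=1.0)
        t = np.array([0.2, 0.5, 1.0, 2.0, 5.0])
        n = 100_000
        ens = mk.simulate_ou_ensemble(p, n, t, step=0.002, seed=3)
        mean, var = mk.ou_moments(t, p)
        se_mean = np.sqrt(var / n)
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(ens.mean - mean) < 3 * se_mean)
        assert np.all(np.abs(ens.variance - var) < 3 * se_var)

    def test_empirical_distribution_matches_closed_form_cdf(self):
        p = mk.OUParameters(D=1.0, eta=1.0, x0=1.0)
        ens = mk.simulate_ou_ensemble(p, 100_000, np.array([1.0]),
                                      step=0.005, seed=9)
        ks = kstest(ens.positions[:, 0],
                    lambda x: mk.ou_cdf(x, 1.0, p)).statistic
        assert ks < 0.01

    def test_unstable_step_rejected(self):
        p = mk.OUParameters(D=1.0, eta=10.0)
        with pytest.raises(ValueError, match="step"):
            mk.simulate_ou_ensemble(p, 5, np.array([1.0]), step=0.06, seed=0)

    def test_same_seed_reproduces_trajectories(self):
        p = mk.OUParameters(D=1.0, eta=1.0, x0=1.0)
        a = mk.simulate_ou_ensemble(p, 50, np.array([0.5, 1.0]), seed=4)
        b = mk.simulate_ou_ensemble(p, 50, np.array([0.5, 1.0]), seed=4)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestReleaseLaw:
    def test_plateau_and_origin(self):
        p = mk.OUParameters(D=2.0, eta=0.5)
        assert mk.release_from_ou(0.0, p) == 0.0
        assert mk.release_from_ou(1e9, p) == pytest.approx(2.0, rel=1e-12)

    def test_early_time_log_log_slope_is_half(self):
        p = mk.OUParameters(D=2.0, eta=0.01)
        t = np.array([1e-4, 2e-4])
        m = mk.release_from_ou(t, p)
        slope = np.diff(np.log(m)) / np.diff(np.log(t))
        assert slope[0] == pytest.approx(0.5, abs=1e-3)


class TestFractalFit:
    def test_single_regime_self_consistency(self):
        t = default_times(300.0, 25, 50.0)
        p = mk.OUParameters(D=2.0, eta=0.01)
        curve = mk.ReleaseCurve("A", 7.4, t, mk.release_from_ou(t, p))
        r = mk.fit_multifractal_release(curve)
        assert r.D_early == pytest.approx(2.0, rel=0.01)
        assert r.D_late == pytest.approx(2.0, rel=0.01)
        assert r.eta_early == pytest.approx(0.01, rel=1e-6)
        assert r.eta_late == pytest.approx(0.01, rel=1e-6)

    def test_noiseless_recovery_to_1e6_relative(self):
        spec = mk.CurveSpec("A", 2.0, plateau_pct=94.1, duration_h=300.0,
                            D_early=1.3, D_late=9.0)
        cfg = mk.PanelConfig(seed=1, generator="two_regime", curves=(spec,),
                             noise_rel=0.0)
        r = mk.fit_multifractal_release(mk.generate_panel(cfg)[0])
        assert r.D_early == pytest.approx(1.3, rel=1e-6)
        assert r.D_late == pytest.approx(9.0, rel=1e-6)

    @pytest.mark.parametrize("d_early,d_late", [(1.3, 9.0), (2.4, 10.0),
                                                (1.1, 6.5), (5.2, 10.4)])
    def test_two_regime_recovery_under_noise(self, d_early, d_late):
        spec = mk.CurveSpec("A", 2.0, plateau_pct=94.1, duration_h=300.0,
                            D_early=d_early, D_late=d_late)
        cfg = mk.PanelConfig(seed=11, generator="two_regime", curves=(spec,),
                             noise_rel=0.02)
        r = mk.fit_multifractal_release(mk.generate_panel(cfg)[0])
        assert r.D_early == pytest.approx(d_early, rel=0.05)
        assert r.D_late == pytest.approx(d_late, rel=0.05)
        assert r.D_late >= r.D_early

    def test_moved_breakpoint_changes_segment_counts(self):
        t = default_times(300.0, 25, 50.0)
        p = mk.OUParameters(D=2.0, eta=0.01)
        curve = mk.ReleaseCurve("A", 7.4, t, mk.release_from_ou(t, p))
        r50 = mk.fit_multifractal_release(curve, breakpoint_h=50.0)
        r100 = mk.fit_multifractal_release(curve, breakpoint_h=100.0)
        assert r100.n_points_early > r50.n_points_early
        assert r100.n_points_late < r50.n_points_late
        assert r100.D_late == pytest.approx(2.0, rel=0.01)

    def test_sparse_segment_rejected(self):
        t = np.array([60.0, 90.0, 120.0, 200.0])
        curve = mk.ReleaseCurve("A", 7.4, t, np.sqrt(t))
        with pytest.raises(ValueError, match="fewer than 3"):
            mk.fit_multifractal_release(curve)


class TestEarlyFractionSolver:
    def test_solution_hits_target(self):
        eta = solve_eta_for_early_fraction(9.0, 28.0, 50.0)
        p = mk.OUParameters(D=9.0, eta=eta)
        assert mk.release_from_ou(50.0, p) == pytest.approx(28.0, rel=1e-8)

    def test_infeasible_target_returns_none(self):
        # sup over eta of release at 50 h is sqrt(2*1.3*50) ~ 11.4
        assert solve_eta_for_early_fraction(1.3, 28.0, 50.0) is None
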