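import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glediff import (
    DoubleWellPotential,
    FreePotential,
    HarmonicPotential,
    MemoryKernel,
    MSDCurve,
    Trajectories,
    alpha_curve,
    analytic_msd,
    expand_geometric,
    GeometricKernelSpec,
    log_time_average_alpha,
    msd_from_trajectories,
    persistence_time,
    regime_classification,
    relaxation_times,
)

from conftest import make_random_kernel


def grid_scan_root(f, lo, hi, n=1_000_000):
    """Independent oracle: sign change on a dense log grid + linear interp."""
    ts = np.geomspace(lo, hi, n)
    vals = f(ts)
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    assert len(idx) >= 1
    i = idx[0]
    t0, t1, f0, f1 = ts[i], ts[i + 1], vals[i], vals[i + 1]
    return t0 - f0 * (t1 - t0) / (f1 - f0)


def make_trajs(x, dt=1.0):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return Trajectories(t=np.arange(x.shape[1]) * dt, x=x)


class TestMsdFromTrajectories:
    def test_ballistic_identity(self):
        t = np.arange(200) * 0.5
        trajs = make_trajs(np.vstack([3.0 * t, 3.0 * t]), dt=0.5)
        msd = msd_from_trajectories(trajs, lags=np.array([0.5, 2.0, 10.0]))
        np.testing.assert_allclose(msd.values, 9.0 * msd.lags**2, rtol=1e-12)

    def test_constant_trajectory_is_zero(self):
        msd = msd_from_trajectories(make_trajs(np.full((1, 100), 2.5)),
                                    lags=np.array([1.0, 5.0]))
        np.testing.assert_array_equal(msd.values, 0.0)

    def test_white_position_surrogate(self):
        # i.i.d. Gaussian positions: MSD = 2 sigma^2 at every lag >= 1
        rng = np.random.default_rng(0)
        sigma = 1.5
        trajs = make_trajs(rng.normal(0, sigma, (64, 4000)))
        msd = msd_from_trajectories(trajs, lags=np.array([1.0, 3.0, 17.0]))
        z = (msd.values - 2 * sigma**2) / msd.stderr
        assert np.max(np.abs(z)) < 3

    def test_long_lags_dropped_with_warning(self):
        trajs = make_trajs(np.arange(50.0)[None, :])
        with pytest.warns(UserWarning):
            msd = msd_from_trajectories(trajs, lags=np.array([1.0, 100.0]))
        assert len(msd.lags) == 1


class TestAlphaCurve:
    @pytest.mark.parametrize("power", [2.0, 1.0])
    def test_exact_power_law(self, power):
        lags = np.geomspace(0.1, 100, 40)
        a = alpha_curve(MSDCurve(lags=lags, values=3.0 * lags**power))
        np.testing.assert_allclose(a.alpha, power, rtol=1e-12)
        assert a.endpoint_mask[0] and a.endpoint_mask[-1]

    def test_constant_msd_zero_slope(self):
        lags = np.geomspace(1, 10, 10)
        a = alpha_curve(MSDCurve(lags=lags, values=np.full(10, 4.0)))
        np.testing.assert_allclose(a.alpha, 0.0, atol=1e-14)

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            alpha_curve(MSDCurve(lags=np.array([1.0, 2.0, 3.0]),
                                 values=np.array([0.0, 1.0, 2.0])))

    def test_smoothing_flagged(self):
        lags = np.geomspace(0.1, 100, 50)
        vals = lags * (1 + 0.2 * np.sin(np.log(lags)))
        a = alpha_curve(MSDCurve(lags=lags, values=vals), smooth_window=5)
        assert a.smooth_window == 5


class TestLogTimeAverageAlpha:
    def test_constant_curve(self):
        lags = np.geomspace(0.01, 100, 60)
        a = alpha_curve(MSDCurve(lags=lags, values=lags**0.5))
        assert log_time_average_alpha(a, 0.1, 10) == pytest.approx(0.5, abs=1e-10)

    def test_collapsed_window_is_pointwise(self):
        lags = np.geomspace(0.1, 10, 30)
        a = alpha_curve(MSDCurve(lags=lags, values=lags**1.3))
        assert log_time_average_alpha(a, 2.0, 2.0) == pytest.approx(1.3, abs=1e-8)

    def test_analytic_pipeline_recovers_closed_form_exponent(self):
        # c=100, d=10, n=9 kernel overdamped at tau_1: oscillations of
        # alpha(t) average to ln(c/d)/ln(c) = 0.5 over [tau_1, tau_n]
        k = expand_geometric(GeometricKernelSpec(1.0, 1.0, 100.0, 10.0, 9))
        curve = analytic_msd(k, K=0.0, B=1.0, t_min=0.03,
                             t_max=3 * k.taus[-1], points_per_decade=12)
        a = alpha_curve(curve)
        est = log_time_average_alpha(a, 1.0, float(k.taus[-1]))
        assert est == pytest.approx(0.5, abs=0.05)

    def test_window_outside_support_rejected(self):
        lags = np.geomspace(1, 10, 10)
        a = alpha_curve(MSDCurve(lags=lags, values=lags))
        with pytest.raises(ValueError):
            log_time_average_alpha(a, 0.1, 5.0)


class TestPersistenceTime:
    def test_markovian_limit_equals_inertial_time(self):
        k = MemoryKernel([1e-4], [1.0])
        assert persistence_time(k) == pytest.approx(1.0, rel=1e-3)

    def test_single_exponential_grid_scan_oracle(self):
        k = MemoryKernel([1.0], [1.0])
        oracle = grid_scan_root(lambda t: t * k.integral(t) - 1.0, 0.1, 100.0)
        assert persistence_time(k) == pytest.approx(oracle, rel=1e-6)

    def test_time_rescaling_covariance(self, three_comp):
        lam = 7.3
        scaled = MemoryKernel(lam * three_comp.taus, three_comp.gammas / lam)
        assert persistence_time(scaled) == pytest.approx(
            lam * persistence_time(three_comp), rel=1e-10
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_exceeds_inertial_time_randomized(self, seed):
        k = make_random_kernel(np.random.default_rng(seed))
        tp = persistence_time(k)
        assert tp >= k.inertial_time * (1 - 1e-12)
        # self-consistency
        assert tp * k.integral(tp) == pytest.approx(1.0, rel=1e-9)


class TestRelaxationTimes:
    def test_double_well_local_relaxation(self, three_comp, double_well):
        rep = relaxation_times(three_comp, double_well, B=1.0)
        assert rep.K_loc == pytest.approx(32.0)
        assert rep.tau_rel_loc == pytest.approx(1.0 / (rep.tau_m * 32.0))
        assert rep.tau_D == pytest.approx(1.0 / (1.0 * rep.tau_m))
        assert rep.D == pytest.approx(rep.tau_m)

    def test_delta_kernel_reduces_to_markovian(self, double_well):
        k = MemoryKernel([1e-7], [2.0])
        rep = relaxation_times(k, double_well, B=1.0)
        assert rep.tau_star_loc == pytest.approx(rep.tau_rel_loc, rel=1e-3)
        assert rep.tau_star_glob == pytest.approx(rep.tau_rel_glob, rel=1e-3)

    def test_long_memory_shortens_relaxation(self, double_well):
        # c=100, d=20, n=3, tau_1 = 1e3 tau_m: slow friction accumulation
        tau_m = 1e-4
        gamma1 = (1.0 / tau_m) / (1 + 20 + 400)
        k = expand_geometric(
            GeometricKernelSpec(gamma1, 1e3 * tau_m, 100.0, 20.0, 3))
        rep = relaxation_times(k, double_well, B=1.0)
        assert rep.tau_star_loc < rep.tau_rel_loc
        assert rep.tau_star_glob < rep.tau_rel_glob
        oracle = grid_scan_root(
            lambda t: t * rep.K_loc - k.integral(t), 1e-6, 1e6)
        assert rep.tau_star_loc == pytest.approx(oracle, rel=1e-6)

    def test_free_potential_only_base_fields(self, three_comp):
        rep = relaxation_times(three_comp, FreePotential(), B=1.0)
        assert rep.K_loc is None and rep.K_glob is None
        assert rep.tau_star_loc is None and rep.tau_star_glob is None
        assert rep.tau_p > 0

    def test_orderings_randomized(self):
        # tau_p >= tau_m; tau* <= Markovian counterpart, for monotone kernels
        rng = np.random.default_rng(33)
        for _ in range(25):
            k = make_random_kernel(rng)
            # double well scaled so K_loc = Gamma(0)/2 < Gamma(0)
            L = np.sqrt(64.0 / k.gamma0)
            rep = relaxation_times(k, DoubleWellPotential(4.0, L), B=1.0)
            assert rep.tau_p >= rep.tau_m * (1 - 1e-12)
            assert rep.tau_star_loc <= rep.tau_rel_loc * (1 + 1e-12)
            assert rep.tau_star_glob <= rep.tau_rel_glob * (1 + 1e-12)


class TestRegimeClassification:
    def test_markovian_free_diffusion(self):
        k = MemoryKernel([1e-6], [1.0])
        curve = analytic_msd(k, K=0.0, t_min=1e-3, t_max=1e3,
                             points_per_decade=12)
        rep = relaxation_times(k, FreePotential())
        segs = regime_classification(curve, rep)
        assert [s.label for s in segs] == ["ballistic", "diffusive"]
        assert segs[0].mean_alpha > 1.5
        assert segs[1].mean_alpha == pytest.approx(1.0, abs=0.15)
        assert segs[0].t_hi == pytest.approx(rep.tau_p)

    def test_harmonic_long_memory_ends_confined(self, three_comp, harmonic):
        curve = analytic_msd(three_comp, K=1.0, t_min=1e-3, t_max=1e4,
                             points_per_decade=10)
        rep = relaxation_times(three_comp, harmonic)
        segs = regime_classification(curve, rep)
        assert segs[-1].label == "confined"
        assert abs(segs[-1].mean_alpha) < 0.2

    def test_double_well_departure_near_local_relaxation(self, double_well):
        # simulated double-well MSD departs from the local-harmonic analytic
        # curve around tau*_loc (first lag with >10% relative deviation)
        from glediff import SimulationConfig, simulate_langevin
        from glediff import evaluate_msd, msd_mode_decomposition

        tau_m = 0.01
        cfg = SimulationConfig(dt=2e-4, n_steps=200_000, n_traj=30, seed=19,
                               stride=20)
        tr = simulate_langevin(double_well, tau_m, cfg)
        msd = msd_from_trajectories(tr, lags_per_decade=6)
        k = MemoryKernel([tau_m * 1e-6], [1.0 / tau_m])
        local = evaluate_msd(msd_mode_decomposition(k, K=32.0, B=1.0),
                             msd.lags)
        rel = np.abs(msd.values - local) / local
        depart = msd.lags[np.argmax(rel > 0.10)]
        rep = relaxation_times(k, double_well, B=1.0)
        assert rep.tau_star_loc / 5 < depart < rep.tau_star_loc * 5
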