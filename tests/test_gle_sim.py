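import numpy as np
import pytest
from scipy.integrate import solve_ivp

from glediff import (
    DoubleWellPotential,
    FreePotential,
    HarmonicPotential,
    MemoryKernel,
    SimulationConfig,
    boltzmann_variance,
    canonical_embedding,
    evaluate_msd,
    init_equilibrium,
    msd_from_trajectories,
    msd_mode_decomposition,
    sample_random_force,
    simulate_gle,
    simulate_langevin,
)


class TestCanonicalEmbedding:
    def test_memory_force_equals_friction_convolution(self, three_comp):
        # impose x(t) = v0 * t (velocity step at t=0), noise off, y_i(0)=x(0):
        # integrating the bath ODEs must give force -v0 * G(t)
        v0 = 1.7
        sde = canonical_embedding(three_comp, B=1.0)

        def rhs(t, y):
            return -(y - v0 * t) / three_comp.taus

        sol = solve_ivp(rhs, (0, 20.0), np.zeros(three_comp.n),
                        t_eval=np.linspace(0.1, 20, 30), rtol=1e-10, atol=1e-12)
        for t, y in zip(sol.t, sol.y.T):
            force = sde.memory_force(np.array([v0 * t]), y[None, :])[0]
            assert force == pytest.approx(-v0 * three_comp.integral(t), rel=1e-7)

    def test_bath_variance_contract(self, three_comp):
        sde = canonical_embedding(three_comp, B=2.0)
        np.testing.assert_allclose(
            sde.bath_variance, 2.0 * three_comp.taus / three_comp.gammas
        )

    def test_invalid_b_rejected(self, three_comp):
        with pytest.raises(ValueError):
            canonical_embedding(three_comp, B=0.0)


class TestFluctuationDissipation:
    def test_force_autocorrelation_matches_kernel(self, three_comp):
        # <F_R(0) F_R(t)> = B * Gamma(t) at t in {0, tau_1, 10 tau_1}
        B, dt = 1.0, 0.005
        n_steps, n_traj = 4000, 200
        t, F = sample_random_force(three_comp, B, dt, n_steps, n_traj, seed=17)
        for lag_t in (0.0, 0.1, 1.0):
            k = int(round(lag_t / dt))
            prod = F[:, : n_steps + 1 - k] * F[:, k:] if k else F * F
            per_traj = prod.mean(axis=1)
            est, se = per_traj.mean(), per_traj.std(ddof=1) / np.sqrt(n_traj)
            assert abs(est - B * three_comp.value(lag_t)) < 3 * se


class TestInitEquilibrium:
    def test_variances(self, three_comp, harmonic):
        cfg = SimulationConfig(dt=1e-3, n_steps=1, n_traj=100_000, seed=2)
        x, v, y = init_equilibrium(three_comp, harmonic, cfg)
        n = cfg.n_traj
        assert abs(x.var() - 1.0) < 3 * np.sqrt(2 / n) * 1.0  # Var(x) = B/K
        assert abs(v.var() - 1.0) < 3 * np.sqrt(2 / n) * 1.0  # Var(v) = B
        offsets = y - x[:, None]
        for i, (tau, gam) in enumerate(zip(three_comp.taus, three_comp.gammas)):
            target = tau / gam
            assert abs(offsets[:, i].var() - target) < 3 * np.sqrt(2 / n) * target

    def test_free_convention_and_determinism(self, three_comp):
        cfg = SimulationConfig(dt=1e-3, n_steps=1, n_traj=100, seed=9)
        x, v, y = init_equilibrium(three_comp, FreePotential(), cfg)
        assert np.all(x == 0.0)
        x2, v2, y2 = init_equilibrium(three_comp, FreePotential(), cfg)
        np.testing.assert_array_equal(v, v2)
        np.testing.assert_array_equal(y, y2)


class TestSimulateGle:
    def test_equipartition_in_harmonic_well(self, three_comp, harmonic):
        cfg = SimulationConfig(dt=0.002, n_steps=40_000, n_traj=60, seed=4,
                               stride=10)
        tr = simulate_gle(three_comp, harmonic, cfg, store_velocity=True)
        # second moments about the known zero mean (per-trajectory sample
        # means are correlated over tau_rel and would bias .var())
        per_traj_var = (tr.x**2).mean(axis=1)
        se = per_traj_var.std(ddof=1) / np.sqrt(tr.n_traj)
        assert abs(per_traj_var.mean() - 1.0) < 3 * se
        per_traj_v = (tr.v**2).mean(axis=1)
        se_v = per_traj_v.std(ddof=1) / np.sqrt(tr.n_traj)
        assert abs(per_traj_v.mean() - 1.0) < 3 * se_v

    def test_free_long_time_diffusivity(self):
        # fitted MSD slope at late lags -> 2 B tau_m within 5%
        k = MemoryKernel([0.05, 0.5], [1.0, 1.0])  # tau_m = 0.5
        cfg = SimulationConfig(dt=0.001, n_steps=200_000, n_traj=60, seed=5,
                               stride=20)
        tr = simulate_gle(k, FreePotential(), cfg)
        msd = msd_from_trajectories(tr)
        late = msd.lags > 100 * k.taus[-1]
        slope = np.polyfit(msd.lags[late], msd.values[late], 1)[0]
        assert slope == pytest.approx(2 * 1.0 * k.inertial_time, rel=0.05)

    def test_matches_analytic_harmonic_msd(self, three_comp, harmonic):
        cfg = SimulationConfig(dt=0.002, n_steps=30_000, n_traj=100, seed=6,
                               stride=2)
        tr = simulate_gle(three_comp, harmonic, cfg)
        msd = msd_from_trajectories(tr, lags_per_decade=4)
        ana = evaluate_msd(msd_mode_decomposition(three_comp, K=1.0, B=1.0),
                           msd.lags)
        z = (msd.values - ana) / msd.stderr
        assert np.max(np.abs(z)) < 3

    def test_dt_stability_guard(self, three_comp, harmonic):
        with pytest.raises(ValueError, match="stability"):
            simulate_gle(three_comp, harmonic,
                         SimulationConfig(dt=0.5, n_steps=10, n_traj=1))

    def test_blow_up_detected(self):
        stiff = HarmonicPotential(K=1e6)
        k = MemoryKernel([1.0], [1.0])
        cfg = SimulationConfig(dt=0.5, n_steps=2000, n_traj=2, seed=0,
                               allow_unstable_dt=True)
        with pytest.raises(FloatingPointError):
            simulate_gle(k, stiff, cfg)

    def test_seed_reproducibility(self, three_comp, harmonic):
        cfg = SimulationConfig(dt=0.002, n_steps=500, n_traj=3, seed=8)
        a = simulate_gle(three_comp, harmonic, cfg)
        b = simulate_gle(three_comp, harmonic, cfg)
        np.testing.assert_array_equal(a.x, b.x)

    def test_dt_halving_within_monte_carlo_error(self, three_comp, harmonic):
        # weak consistency: halving dt moves the MSD by less than the
        # statistical error at every reported lag
        lags = np.geomspace(0.05, 5.0, 8)
        curves = []
        for dt, stride in ((0.002, 5), (0.001, 10)):
            cfg = SimulationConfig(dt=dt, n_steps=int(20.0 / dt), n_traj=60,
                                   seed=12, stride=stride)
            tr = simulate_gle(three_comp, harmonic, cfg)
            curves.append(msd_from_trajectories(tr, lags=lags))
        diff = np.abs(curves[0].values - curves[1].values)
        err = np.hypot(curves[0].stderr, curves[1].stderr)
        assert np.all(diff < 3 * err)


class TestSimulateLangevin:
    def test_free_msd_matches_closed_form(self):
        tau_m, B = 0.5, 1.0
        cfg = SimulationConfig(dt=0.005, n_steps=40_000, n_traj=80, seed=3,
                               stride=4)
        tr = simulate_langevin(FreePotential(), tau_m, cfg)
        msd = msd_from_trajectories(tr, lags_per_decade=4)
        t = msd.lags
        exact = 2 * B * tau_m**2 * (t / tau_m - 1 + np.exp(-t / tau_m))
        z = (msd.values - exact) / msd.stderr
        assert np.max(np.abs(z)) < 3

    def test_double_well_regime_ordering(self):
        # overdamped double well: diffusive stretch, then the local well
        # and slow barrier crossing bend the MSD toward confinement
        pot = DoubleWellPotential(U0=4.0, L=1.0)
        cfg = SimulationConfig(dt=2e-4, n_steps=400_000, n_traj=30, seed=7,
                               stride=40)
        tr = simulate_langevin(pot, tau_m=0.01, cfg=cfg)
        msd = msd_from_trajectories(tr, lags_per_decade=4)
        slopes = np.gradient(np.log(msd.values), np.log(msd.lags))
        mid = slopes[(msd.lags > 0.1) & (msd.lags < 0.6)]
        late = slopes[msd.lags > 10.0]
        assert mid.mean() > 0.8          # near-diffusive stretch
        assert late.mean() < 0.5         # confinement onset
        assert late.mean() < mid.mean()

    def test_markovian_limit_agrees_with_gle(self, harmonic):
        tau_m = 0.5
        k = MemoryKernel([tau_m * 1e-2], [1.0 / tau_m])
        lags = np.geomspace(0.05, 5.0, 9)
        cfg_g = SimulationConfig(dt=1e-4, n_steps=200_000, n_traj=40, seed=10,
                                 stride=50)
        msd_g = msd_from_trajectories(simulate_gle(k, harmonic, cfg_g), lags=lags)
        cfg_l = SimulationConfig(dt=5e-3, n_steps=4000, n_traj=40, seed=11)
        msd_l = msd_from_trajectories(
            simulate_langevin(harmonic, tau_m, cfg_l), lags=lags)
        z = (msd_g.values - msd_l.values) / np.hypot(msd_g.stderr, msd_l.stderr)
        assert np.max(np.abs(z)) < 3

    def test_invalid_tau_m(self, harmonic):
        with pytest.raises(ValueError):
            simulate_langevin(harmonic, -1.0,
                              SimulationConfig(dt=1e-3, n_steps=10))
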