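"""GLE simulation via Markovian embedding, and its Markovian Langevin limit.

A GLE with multi-exponential kernel is rewritten exactly as a memoryless
system by coupling the coordinate to one Ornstein-Uhlenbeck bath variable
per kernel component:

    dx    = v dt
    dv    = [-U'(x) + sum_i (gamma_i/tau_i) (y_i - x)] dt
    dy_i  = -(y_i - x)/tau_i dt + sqrt(2 B / gamma_i) dW_i

Eliminating the ``y_i`` recovers the friction integral with
``Gamma(t) = sum_i (gamma_i/tau_i) e^{-t/tau_i}`` and a random force whose
autocorrelation is ``B Gamma(t)`` (the equilibrium fluctuation-dissipation
relation).  The extended system is Hamiltonian-plus-bath with stationary
density ``exp(-[U(x) + v^2/2 + sum_i (gamma_i/2 tau_i)(y_i - x)^2]/B)``, so
equilibrium initial conditions are ``x ~ e^{-U/B}``, ``v ~ N(0, B)``,
``y_i = x + N(0, B tau_i / gamma_i)``.

Integrator: a splitting scheme — exact OU half-steps for each bath variable
(at frozen x) around a velocity-Verlet step for (x, v) under the combined
potential and bath-coupling force.  The OU parts are integrated exactly, so
the scheme stays stable across the many-decade time-scale spreads of
geometric kernels, where naive Euler-Maruyama fails.

When all memory times are short compared to the inertial time the GLE
reduces to the Markovian Langevin equation
``xddot = -U'(x) - xdot/tau_m + F_R`` with white noise of intensity
``2 B / tau_m``; :func:`simulate_langevin` integrates it with BAOAB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import MemoryKernel
from .potentials import FreePotential, Potential, boltzmann_sample, local_stiffness

__all__ = [
    "SimulationConfig",
    "EmbeddedSDE",
    "Trajectories",
    "canonical_embedding",
    "init_equilibrium",
    "simulate_gle",
    "simulate_langevin",
    "sample_random_force",
]

logger = logging.getLogger(__name__)

# dt must resolve the fastest of (tau_1, tau_m, 1/sqrt(K_loc)) by this factor
_STABILITY_FACTOR = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt : integrator step (time); must satisfy the stability bound
        ``dt <= min(tau_1, tau_m, K_loc**-0.5) / 50`` unless
        ``allow_unstable_dt`` is set.
    n_steps : number of integration steps.
    n_traj : independent trajectories (paper-scale ensembles use 1000).
    seed : root RNG seed; a fixed (config, seed) pair is bit-reproducible.
    stride : output decimation (every ``stride``-th step is stored).
    B : velocity variance ``<xdot^2>`` (length^2/time^2), the thermal scale.
    """

    dt: float
    n_steps: int
    n_traj: int = 1
    seed: int = 0
    stride: int = 1
    B: float = 1.0
    allow_unstable_dt: bool = False

    def __post_init__(self):
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ValueError("dt must be positive and finite")
        if self.n_steps < 1 or self.n_traj < 1 or self.stride < 1:
            raise ValueError("n_steps, n_traj and stride must be >= 1")
        if self.B <= 0:
            raise ValueError("B must be positive")


@dataclass(frozen=True)
class EmbeddedSDE:
    """Markovian embedding of a multi-exponential GLE (see module docstring)."""

    kernel: MemoryKernel
    B: float

    @property
    def coupling(self) -> np.ndarray:
        """Spring rates ``k_i = gamma_i / tau_i`` (1/time^2)."""
        return self.kernel.gammas / self.kernel.taus

    @property
    def bath_variance(self) -> np.ndarray:
        """Stationary Var(y_i - x) at frozen x: ``B tau_i / gamma_i``."""
        return self.B * self.kernel.taus / self.kernel.gammas

    def memory_force(self, x, y) -> np.ndarray:
        """Friction + random force carried by the baths: sum_i k_i (y_i - x)."""
        return (self.coupling[None, :] * (y - x[:, None])).sum(axis=1)


def canonical_embedding(kernel: MemoryKernel, B: float = 1.0) -> EmbeddedSDE:
    """Build the OU-coupled embedded SDE for ``kernel`` at thermal scale ``B``."""
    if B <= 0:
        raise ValueError("B must be positive")
    return EmbeddedSDE(kernel=kernel, B=B)


@dataclass
class Trajectories:
    """Ensemble of simulated trajectories on a common uniform time grid."""

    t: np.ndarray  # (n_frames,)
    x: np.ndarray  # (n_traj, n_frames)
    v: np.ndarray | None = None
    B: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_traj(self) -> int:
        return self.x.shape[0]

    @property
    def dt_out(self) -> float:
        return float(self.t[1] - self.t[0])


def _stability_dt(kernel: MemoryKernel | None, potential: Potential,
                  tau_m: float) -> float:
    scales = [tau_m]
    if kernel is not None:
        scales.append(float(kernel.taus[0]))
    try:
        scales.append(1.0 / np.sqrt(local_stiffness(potential)))
    except (ValueError, NotImplementedError):
        pass
    return min(scales) / _STABILITY_FACTOR


def _check_dt(cfg: SimulationConfig, bound: float):
    if cfg.dt > bound and not cfg.allow_unstable_dt:
        raise ValueError(
            f"dt={cfg.dt:g} exceeds the stability bound {bound:g} "
            "(min(tau_1, tau_m, K_loc**-0.5)/50); pass allow_unstable_dt=True "
            "to override"
        )


def init_equilibrium(
    kernel: MemoryKernel | None,
    potential: Potential,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Equilibrium initial conditions for ``n_traj`` trajectories.

    Returns ``(x0, v0, y0)`` with ``x0 ~ e^{-U/B}`` (or 0 for the free
    potential, where the MSD is translation invariant), ``v0 ~ N(0, B)`` and
    bath offsets ``y0_i - x0 ~ N(0, B tau_i/gamma_i)`` independent across
    components and trajectories.  ``y0`` is None when ``kernel`` is None
    (Markovian simulation).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if potential.confining:
        x0 = boltzmann_sample(
            potential, cfg.B, cfg.n_traj,
            seed=int(rng.integers(2**31)),
        )
    elif isinstance(potential, (FreePotential,)) or not potential.confining:
        x0 = np.zeros(cfg.n_traj)
    v0 = rng.normal(0.0, np.sqrt(cfg.B), cfg.n_traj)
    y0 = None
    if kernel is not None:
        sde = canonical_embedding(kernel, cfg.B)
        y0 = x0[:, None] + rng.normal(
            0.0, 1.0, (cfg.n_traj, kernel.n)
        ) * np.sqrt(sde.bath_variance)[None, :]
    return x0, v0, y0


def _log_timescales(kernel: MemoryKernel | None, tau_m: float, cfg, bound):
    logger.info(
        "simulation start: dt=%g (stability bound %g), n_steps=%d, n_traj=%d, "
        "tau_m=%g%s",
        cfg.dt, bound, cfg.n_steps, cfg.n_traj, tau_m,
        "" if kernel is None else f", taus={kernel.taus.tolist()}",
    )


def simulate_gle(
    kernel: MemoryKernel,
    potential: Potential,
    cfg: SimulationConfig,
    store_velocity: bool = False,
) -> Trajectories:
    """Integrate the embedded GLE; returns the trajectory ensemble.

    The splitting per step dt is: exact OU half-step for every bath variable,
    velocity-Verlet for (x, v) under ``-U'(x) + sum_i k_i (y_i - x)``, exact
    OU half-step again.  Equilibrium initial conditions are drawn internally
    from ``cfg.seed``.
    """
    sde = canonical_embedding(kernel, cfg.B)
    tau_m = kernel.inertial_time
    bound = _stability_dt(kernel, potential, tau_m)
    _check_dt(cfg, bound)
    _log_timescales(kernel, tau_m, cfg, bound)

    rng = np.random.default_rng(cfg.seed)
    x, v, y = init_equilibrium(kernel, potential, cfg, rng)

    h = 0.5 * cfg.dt
    decay = np.exp(-h / kernel.taus)  # (n,)
    kick = np.sqrt(sde.bath_variance * (1.0 - decay**2))  # (n,)
    k_coup = sde.coupling

    n_frames = cfg.n_steps // cfg.stride + 1
    out_x = np.empty((cfg.n_traj, n_frames))
    out_v = np.empty_like(out_x) if store_velocity else None
    out_x[:, 0] = x
    if store_velocity:
        out_v[:, 0] = v

    def force(x, y):
        return -potential.grad(x) + (k_coup[None, :] * (y - x[:, None])).sum(axis=1)

    frame = 1
    f = force(x, y)
    for step in range(1, cfg.n_steps + 1):
        # OU half-step for baths (x frozen)
        noise = rng.standard_normal((cfg.n_traj, kernel.n))
        y = x[:, None] + (y - x[:, None]) * decay[None, :] + noise * kick[None, :]
        # velocity Verlet on (x, v)
        f = force(x, y)
        v = v + h * f
        x = x + cfg.dt * v
        f = force(x, y)
        v = v + h * f
        # OU half-step again
        noise = rng.standard_normal((cfg.n_traj, kernel.n))
        y = x[:, None] + (y - x[:, None]) * decay[None, :] + noise * kick[None, :]

        if step % cfg.stride == 0:
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
                raise FloatingPointError(
                    f"numeric blow-up at step {step}; reduce dt "
                    f"(current dt={cfg.dt:g}, bound {bound:g})"
                )
            out_x[:, frame] = x
            if store_velocity:
                out_v[:, frame] = v
            frame += 1

    t = np.arange(n_frames) * (cfg.dt * cfg.stride)
    return Trajectories(
        t=t, x=out_x, v=out_v, B=cfg.B,
        meta={
            "provenance": "simulated", "model": "gle",
            "taus": kernel.taus.tolist(), "gammas": kernel.gammas.tolist(),
            "potential": potential.kind, "dt": cfg.dt, "seed": cfg.seed,
        },
    )


def simulate_langevin(
    potential: Potential,
    tau_m: float,
    cfg: SimulationConfig,
    store_velocity: bool = False,
) -> Trajectories:
    """Markovian Langevin dynamics ``xddot = -U'(x) - xdot/tau_m + F_R``.

    White-noise intensity ``2 B / tau_m``; integrated with BAOAB (exact OU
    sub-step for the friction + noise part).  Matches :func:`simulate_gle`
    statistics when all memory times are far below ``tau_m``.
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    bound = _stability_dt(None, potential, tau_m)
    _check_dt(cfg, bound)
    _log_timescales(None, tau_m, cfg, bound)

    rng = np.random.default_rng(cfg.seed)
    x, v, _ = init_equilibrium(None, potential, cfg, rng)

    h = 0.5 * cfg.dt
    c = np.exp(-cfg.dt / tau_m)
    sigma = np.sqrt(cfg.B * (1.0 - c * c))

    n_frames = cfg.n_steps // cfg.stride + 1
    out_x = np.empty((cfg.n_traj, n_frames))
    out_v = np.empty_like(out_x) if store_velocity else None
    out_x[:, 0] = x
    if store_velocity:
        out_v[:, 0] = v

    frame = 1
    for step in range(1, cfg.n_steps + 1):
        v = v - h * potential.grad(x)
        x = x + h * v
        v = c * v + sigma * rng.standard_normal(cfg.n_traj)
        x = x + h * v
        v = v - h * potential.grad(x)
        if step % cfg.stride == 0:
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
                raise FloatingPointError(
                    f"numeric blow-up at step {step}; reduce dt"
                )
            out_x[:, frame] = x
            if store_velocity:
                out_v[:, frame] = v
            frame += 1

    t = np.arange(n_frames) * (cfg.dt * cfg.stride)
    return Trajectories(
        t=t, x=out_x, v=out_v, B=cfg.B,
        meta={
            "provenance": "simulated", "model": "langevin", "tau_m": tau_m,
            "potential": potential.kind, "dt": cfg.dt, "seed": cfg.seed,
        },
    )


def sample_random_force(
    kernel: MemoryKernel,
    B: float,
    dt: float,
    n_steps: int,
    n_traj: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the effective random force of the embedding at frozen x.

    With the coordinate pinned at the origin the bath variables are
    independent OU processes and the random force
    ``F_R(t) = sum_i (gamma_i/tau_i) y_i(t)`` has autocorrelation
    ``B Gamma(t)`` — the fluctuation-dissipation relation.  Returns
    ``(t, F)`` with ``F`` of shape (n_traj, n_steps+1), using the exact OU
    update so arbitrary dt is legal.
    """
    sde = canonical_embedding(kernel, B)
    rng = np.random.default_rng(seed)
    decay = np.exp(-dt / kernel.taus)
    kick = np.sqrt(sde.bath_variance * (1.0 - decay**2))
    y = rng.normal(0.0, 1.0, (n_traj, kernel.n)) * np.sqrt(sde.bath_variance)
    out = np.empty((n_traj, n_steps + 1))
    out[:, 0] = (sde.coupling[None, :] * y).sum(axis=1)
    for step in range(1, n_steps + 1):
        y = y * decay[None, :] + rng.standard_normal((n_traj, kernel.n)) * kick[None, :]
        out[:, step] = (sde.coupling[None, :] * y).sum(axis=1)
    return np.arange(n_steps + 1) * dt, out
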