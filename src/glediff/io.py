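"""File formats, run configuration, fixtures and figure-style sweeps.

Formats (all plain text, human-diffable):

* kernel JSON — ``{"gammas": [...], "taus": [...]}`` or
  ``{"geometric": {"gamma1":, "tau1":, "c":, "d":, "n":}}``; the writer
  emits the expanded explicit form plus the generating spec when known.
* potential JSON — ``{"kind": "double_well", "U0":, "L":}`` etc.; tabulated
  landscapes also as two-column TSV (x, U) with a header line.
* kernel samples TSV — two columns (t, gamma) with a header line.
* curves TSV — columns t, msd[, stderr] and t, alpha.
* trajectories TSV — columns traj_id, t, x[, v]; an HDF5 container
  (one dataset per trajectory) is available when h5py is installed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytic_msd import analytic_msd
from .gle_sim import SimulationConfig, Trajectories, simulate_gle, simulate_langevin
from .kernels import GeometricKernelSpec, MemoryKernel, expand_geometric
from .msd_analysis import (
    AlphaCurve,
    MSDCurve,
    Segment,
    alpha_curve,
    msd_from_trajectories,
    regime_classification,
    relaxation_times,
)
from .potentials import (
    DoubleWellPotential,
    FreePotential,
    HarmonicPotential,
    Potential,
    TabulatedPotential,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_kernel", "save_kernel", "read_kernel_samples",
    "load_potential", "save_potential", "read_potential_table",
    "write_msd_tsv", "read_msd_tsv", "write_alpha_tsv",
    "write_trajectories_tsv", "read_trajectories_tsv",
    "write_trajectories_h5", "read_trajectories_h5",
    "RunConfig", "config_hash", "run", "regime_report",
    "emit_fixture", "run_figure_sweep",
]


# ---------------------------------------------------------------- kernels

def load_kernel(path) -> MemoryKernel:
    """Read a kernel JSON (explicit or geometric form)."""
    obj = json.loads(Path(path).read_text())
    return kernel_from_dict(obj)


def kernel_from_dict(obj: dict) -> MemoryKernel:
    if "geometric" in obj:
        g = obj["geometric"]
        return expand_geometric(GeometricKernelSpec(
            gamma1=g["gamma1"], tau1=g["tau1"], c=g["c"], d=g["d"], n=g["n"]))
    return MemoryKernel(obj["taus"], obj["gammas"])


def save_kernel(kernel: MemoryKernel, path,
                spec: GeometricKernelSpec | None = None) -> None:
    obj = {"taus": kernel.taus.tolist(), "gammas": kernel.gammas.tolist()}
    if spec is not None:
        obj["geometric"] = {"gamma1": spec.gamma1, "tau1": spec.tau1,
                            "c": spec.c, "d": spec.d, "n": spec.n}
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_kernel_samples(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column TSV (t, gamma) with header -> sample arrays for fitting."""
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


# -------------------------------------------------------------- potentials

def load_potential(path) -> Potential:
    return potential_from_dict(json.loads(Path(path).read_text()))


def potential_from_dict(obj: dict) -> Potential:
    kind = obj["kind"]
    if kind == "free":
        return FreePotential()
    if kind == "harmonic":
        return HarmonicPotential(K=obj["K"])
    if kind == "double_well":
        return DoubleWellPotential(U0=obj["U0"], L=obj["L"])
    if kind == "tabulated":
        return TabulatedPotential(obj["x"], obj["U"])
    raise ValueError(f"unknown potential kind {kind!r}")


def save_potential(p: Potential, path) -> None:
    if isinstance(p, FreePotential):
        obj = {"kind": "free"}
    elif isinstance(p, HarmonicPotential):
        obj = {"kind": "harmonic", "K": p.K}
    elif isinstance(p, DoubleWellPotential):
        obj = {"kind": "double_well", "U0": p.U0, "L": p.L}
    elif isinstance(p, TabulatedPotential):
        obj = {"kind": "tabulated", "x": p.x.tolist(), "U": p.U.tolist()}
    else:
        raise ValueError(f"cannot serialize potential {p!r}")
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_potential_table(path) -> TabulatedPotential:
    """Two-column TSV (x, U) with header -> tabulated landscape (e.g. a PMF)."""
    df = pd.read_csv(path, sep="\t")
    return TabulatedPotential(df.iloc[:, 0].to_numpy(float),
                              df.iloc[:, 1].to_numpy(float))


# ------------------------------------------------------------------ curves

def write_msd_tsv(curve: MSDCurve, path, alpha: AlphaCurve | None = None) -> None:
    cols = {"t": curve.lags, "msd": curve.values}
    if curve.stderr is not None:
        cols["stderr"] = curve.stderr
    if alpha is not None:
        cols["alpha"] = np.interp(np.log(curve.lags), np.log(alpha.times),
                                  alpha.alpha)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_msd_tsv(path) -> MSDCurve:
    df = pd.read_csv(path, sep="\t")
    return MSDCurve(
        lags=df["t"].to_numpy(float), values=df["msd"].to_numpy(float),
        stderr=df["stderr"].to_numpy(float) if "stderr" in df else None,
    )


def write_alpha_tsv(alpha: AlphaCurve, path) -> None:
    pd.DataFrame({"t": alpha.times, "alpha": alpha.alpha}).to_csv(
        path, sep="\t", index=False)


# ------------------------------------------------------------ trajectories

def write_trajectories_tsv(trajs: Trajectories, path,
                           with_velocity: bool = False) -> None:
    n_traj, n_frames = trajs.x.shape
    cols = {
        "traj_id": np.repeat(np.arange(n_traj), n_frames),
        "t": np.tile(trajs.t, n_traj),
        "x": trajs.x.ravel(),
    }
    if with_velocity and trajs.v is not None:
        cols["v"] = trajs.v.ravel()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_trajectories_tsv(path, B: float = 1.0) -> Trajectories:
    df = pd.read_csv(path, sep="\t")
    ids = df["traj_id"].to_numpy(int)
    n_traj = ids.max() + 1
    n_frames = (ids == 0).sum()
    t = df["t"].to_numpy(float)[:n_frames]
    x = df["x"].to_numpy(float).reshape(n_traj, n_frames)
    v = df["v"].to_numpy(float).reshape(n_traj, n_frames) if "v" in df else None
    return Trajectories(t=t, x=x, v=v, B=B, meta={"provenance": "loaded"})


def write_trajectories_h5(trajs: Trajectories, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=trajs.t)
        grp = f.create_group("x")
        for i in range(trajs.n_traj):
            grp.create_dataset(str(i), data=trajs.x[i])
        f.attrs["B"] = trajs.B


def read_trajectories_h5(path) -> Trajectories:
    import h5py

    with h5py.File(path, "r") as f:
        t = f["t"][:]
        keys = sorted(f["x"].keys(), key=int)
        x = np.stack([f["x"][k][:] for k in keys])
        B = float(f.attrs.get("B", 1.0))
    return Trajectories(t=t, x=x, B=B, meta={"provenance": "loaded"})


# ---------------------------------------------------------------- run config

@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one simulation + analysis run."""

    kernel: dict
    potential: dict
    B: float = 1.0
    dt: float | None = None
    n_steps: int = 100_000
    n_traj: int = 100
    seed: int = 0
    stride: int = 1
    lags_per_decade: int = 8
    smooth_window: int = 1
    model: str = "gle"  # gle | langevin
    tau_m: float | None = None  # langevin only

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]


def _resolve_dt(cfg: RunConfig, kernel, potential) -> float:
    from .gle_sim import _stability_dt

    if cfg.dt is not None:
        return cfg.dt
    tau_m = kernel.inertial_time if kernel is not None else cfg.tau_m
    return _stability_dt(kernel, potential, tau_m) / 2.0


def run(cfg: RunConfig):
    """Execute a run config: simulate, estimate MSD/alpha, classify regimes.

    Returns (Trajectories, MSDCurve, AlphaCurve, TimescaleReport, segments).
    Re-executing the same config (same hash) is bit-identical.
    """
    kernel = kernel_from_dict(cfg.kernel) if cfg.model == "gle" else None
    potential = potential_from_dict(cfg.potential)
    dt = _resolve_dt(cfg, kernel, potential)
    sim_cfg = SimulationConfig(dt=dt, n_steps=cfg.n_steps, n_traj=cfg.n_traj,
                               seed=cfg.seed, stride=cfg.stride, B=cfg.B)
    if cfg.model == "gle":
        trajs = simulate_gle(kernel, potential, sim_cfg)
        report_kernel = kernel
    elif cfg.model == "langevin":
        if cfg.tau_m is None:
            raise ValueError("langevin model requires tau_m")
        trajs = simulate_langevin(potential, cfg.tau_m, sim_cfg)
        # delta-like surrogate kernel so timescale formulas apply
        report_kernel = MemoryKernel([cfg.tau_m * 1e-8], [1.0 / cfg.tau_m])
    else:
        raise ValueError(f"unknown model {cfg.model!r}")
    msd = msd_from_trajectories(trajs, lags_per_decade=cfg.lags_per_decade)
    alpha = alpha_curve(msd, smooth_window=cfg.smooth_window)
    report = relaxation_times(report_kernel, potential, cfg.B)
    segments = regime_classification(msd, report)
    return trajs, msd, alpha, report, segments


def regime_report(cfg: RunConfig, report, segments: list[Segment]) -> dict:
    """JSON-ready regime report referencing the producing config hash."""
    return {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "timescales": {k: (None if v is None or not np.isfinite(v) else float(v))
                       for k, v in asdict(report).items()},
        "segments": [asdict(s) for s in segments],
    }


# ------------------------------------------------------------------ fixtures

def emit_fixture(kind: str, seed: int, out_dir) -> Path:
    """Write a small deterministic fixture file; returns its path.

    kinds: ``kernel`` (3-component), ``potential`` (double well, U0=4, L=1),
    ``trajectory`` (10-trajectory Langevin run in that double well).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "kernel":
        path = out_dir / "kernel_fixture.json"
        save_kernel(MemoryKernel([0.1, 1.0, 10.0], [1.0, 2.0, 4.0]), path)
    elif kind == "potential":
        path = out_dir / "potential_fixture.json"
        save_potential(DoubleWellPotential(U0=4.0, L=1.0), path)
    elif kind == "trajectory":
        path = out_dir / "trajectory_fixture.tsv"
        pot = DoubleWellPotential(U0=4.0, L=1.0)
        cfg = SimulationConfig(dt=1e-3, n_steps=2000, n_traj=10,
                               seed=seed, stride=10, B=1.0)
        trajs = simulate_langevin(pot, tau_m=0.1, cfg=cfg)
        write_trajectories_tsv(trajs, path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         "choose kernel | potential | trajectory")
    return path


# ------------------------------------------------------------- figure sweeps

def _geometric_unit_tau_m(c: float, d: float, n: int) -> MemoryKernel:
    """Geometric kernel normalized to tau_m = 1 with tau_1 = tau_m."""
    gamma1 = 1.0 / sum(d**i for i in range(n))
    return expand_geometric(GeometricKernelSpec(
        gamma1=gamma1, tau1=1.0, c=c, d=d, n=n))


def run_figure_sweep(preset: str, scale: str = "reduced", out_dir=".",
                     seed: int = 0) -> list[Path]:
    """Parameter sweeps mirroring the study's figure layouts.

    * ``fig2`` — analytic free-diffusion MSDs and alpha(t) for geometric
      kernels (n=5, tau_1 = tau_m) over c in {0.1, 10, 100} and
      d in {0.1, 1, 5, 10, 20}.  Deterministic.
    * ``fig4`` — analytic MSDs in harmonic confinement: memoryless limits
      and an n=3 memory kernel across K values.  Deterministic.
    * ``fig5`` — memoryless (Langevin) simulations in a double well:
      a tau_m grid at U0 = 2B and a U0 grid at fixed tau_m.
    * ``fig6`` — GLE simulations in a double well with n=3 geometric memory
      (c=100, d in {5, 20}, tau_1 = 1e3 tau_m) over a U0 grid.  The study's
      tau_m = 1e-8 tau_D spans 11+ decades; scale="reduced" substitutes
      tau_m = 1e-4 tau_D (scale="full" uses 1e-6) with the same qualitative
      regime sequence.

    Writes TSV curves and JSON regime reports under ``out_dir``; returns the
    written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    reduced = scale == "reduced"
    if scale not in ("full", "reduced"):
        raise ValueError("scale must be 'full' or 'reduced'")

    def emit_analytic(tag: str, kernel: MemoryKernel, K: float):
        curve = analytic_msd(kernel, K=K, B=1.0,
                             points_per_decade=8 if reduced else 16)
        a = alpha_curve(curve, smooth_window=1)
        p1 = out_dir / f"{tag}_msd.tsv"
        write_msd_tsv(curve, p1, alpha=a)
        written.append(p1)

    def emit_run(tag: str, cfg: RunConfig):
        trajs, msd, alpha, report, segments = run(cfg)
        p1 = out_dir / f"{tag}_msd.tsv"
        write_msd_tsv(msd, p1, alpha=alpha)
        p2 = out_dir / f"{tag}_regimes.json"
        p2.write_text(json.dumps(regime_report(cfg, report, segments), indent=1))
        written.extend([p1, p2])

    if preset == "fig2":
        for c in (0.1, 10.0, 100.0):
            for d in (0.1, 1.0, 5.0, 10.0, 20.0):
                emit_analytic(f"fig2_c{c:g}_d{d:g}",
                              _geometric_unit_tau_m(c, d, 5), K=0.0)
    elif preset == "fig4":
        for K in (0.01, 1.0, 100.0):
            emit_analytic(f"fig4_markovian_K{K:g}",
                          MemoryKernel([1e-8], [1.0]), K=K)
            emit_analytic(f"fig4_memory_K{K:g}",
                          _geometric_unit_tau_m(10.0, 5.0, 3), K=K)
    elif preset == "fig5":
        n_steps = 200_000 if reduced else 2_000_000
        n_traj = 50 if reduced else 1000
        pot = {"kind": "double_well", "U0": 2.0, "L": 1.0}
        for tau_m in (1e-2, 1e-1) if reduced else (1e-4, 1e-3, 1e-2):
            cfg = RunConfig(kernel={}, potential=pot, model="langevin",
                            tau_m=tau_m, n_steps=n_steps, n_traj=n_traj,
                            seed=seed, stride=20, smooth_window=3)
            emit_run(f"fig5_taum{tau_m:g}", cfg)
        for U0 in (0.5, 1.0, 2.0, 4.0):
            cfg = RunConfig(kernel={}, potential={**pot, "U0": U0},
                            model="langevin", tau_m=1e-2, n_steps=n_steps,
                            n_traj=n_traj, seed=seed, stride=20,
                            smooth_window=3)
            emit_run(f"fig5_U0{U0:g}", cfg)
    elif preset == "fig6":
        # tau_m set by tau_m = f * tau_D with tau_D = L^2/(B tau_m), L=B=1
        f_ratio = 1e-4 if reduced else 1e-6
        tau_m = float(np.sqrt(f_ratio))
        n_steps = 400_000 if reduced else 5_000_000
        n_traj = 50 if reduced else 1000
        for d in (5.0, 20.0):
            gamma1 = (1.0 / tau_m) / sum(d**i for i in range(3))
            kern = {"geometric": {"gamma1": gamma1, "tau1": 1e3 * tau_m,
                                  "c": 100.0, "d": d, "n": 3}}
            for U0 in (0.5, 1.0, 2.0, 4.0):
                cfg = RunConfig(kernel=kern,
                                potential={"kind": "double_well", "U0": U0,
                                           "L": 1.0},
                                model="gle", n_steps=n_steps, n_traj=n_traj,
                                seed=seed, stride=20, smooth_window=3)
                emit_run(f"fig6_d{d:g}_U0{U0:g}", cfg)
    else:
        raise ValueError(
            f"unknown preset {preset!r}; choose fig2 | fig4 | fig5 | fig6")
    return written
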