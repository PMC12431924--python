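"""MSD and time-dependent exponent estimation, and the derived time scales.

The mode of diffusion at lag t is classified by the log-log slope of the
mean squared displacement,

    alpha(t) = d ln C_MSD(t) / d ln t,

with alpha = 2 ballistic, 1 diffusive, < 1 subdiffusive and -> 0 confined.
Several self-consistent time scales delimit these regimes:

* inertial time ``tau_m = 1 / G(inf)``,
* persistence time ``tau_p``: solution of ``tau * G(tau) = 1``; end of the
  ballistic regime, equal to ``tau_m`` when all memory times are short,
  prolonged (``tau_p > tau_m``) by slow friction accumulation,
* Markovian harmonic relaxation time ``tau_rel = 1/(tau_m K)``, and its
  memory generalizations ``tau* = G(tau*)/K`` evaluated with the local
  (``K_loc``) or global (``K_glob``) stiffness of the landscape — the
  time at which accumulated friction is balanced by the harmonic
  restoring force,
* diffusion time ``tau_D = L**2 / (B tau_m)`` across the well-to-barrier
  distance of a double well.

Because ``G`` is increasing and bounded, each self-consistent equation has
at most one positive root; roots are found by guaranteed bracketing
(Brent) with a grid-free bracket expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .gle_sim import Trajectories
from .kernels import MemoryKernel
from .potentials import (
    DoubleWellPotential,
    Potential,
    global_stiffness,
    local_stiffness,
)

__all__ = [
    "MSDCurve",
    "AlphaCurve",
    "TimescaleReport",
    "Segment",
    "msd_from_trajectories",
    "alpha_curve",
    "log_time_average_alpha",
    "persistence_time",
    "relaxation_times",
    "regime_classification",
]


@dataclass
class MSDCurve:
    """MSD values on a (log-spaced by default) lag grid.

    ``stderr`` holds across-trajectory standard errors when the curve is
    estimated from an ensemble; analytic curves carry None.  ``meta``
    records provenance (analytic | simulated), B and the generating
    kernel/potential parameters.
    """

    lags: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.values.shape:
            raise ValueError("lags and values must be 1-D of equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be non-negative")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)


@dataclass
class AlphaCurve:
    """Time-dependent exponent alpha(t) on a log-spaced grid.

    ``smooth_window`` > 1 flags a moving-average smoothed variant;
    ``endpoint_mask`` marks the two one-sided-stencil boundary points.
    """

    times: np.ndarray
    alpha: np.ndarray
    smooth_window: int = 1
    endpoint_mask: np.ndarray | None = None


@dataclass
class TimescaleReport:
    """Derived time scales of a (kernel, potential, B) system.

    Fields that need a confining potential (or a local minimum) are None
    when the potential does not provide them.  ``tau_star_loc`` /
    ``tau_star_glob`` are the memory-aware self-consistent relaxation times;
    their Markovian counterparts are ``tau_rel_loc`` / ``tau_rel_glob``.
    """

    tau_m: float
    tau_p: float
    D: float
    B: float
    K_loc: float | None = None
    K_glob: float | None = None
    tau_rel_loc: float | None = None
    tau_rel_glob: float | None = None
    tau_star_loc: float | None = None
    tau_star_glob: float | None = None
    tau_D: float | None = None


def msd_from_trajectories(trajs: Trajectories, lags=None,
                          lags_per_decade: int = 8) -> MSDCurve:
    """Time- and ensemble-averaged MSD of a trajectory ensemble.

    Per trajectory the MSD at lag ``tau = k*dt`` averages
    ``(x(t0 + tau) - x(t0))**2`` over *all* sliding origins ``t0`` (the
    standard overlapping-origin estimator); trajectories are then averaged
    and the across-trajectory spread provides the standard error (origins
    within one trajectory are strongly correlated, so only the ensemble
    spread is meaningful).

    ``lags`` are absolute lag times, rounded to multiples of the sampling
    interval; by default a log-spaced grid with ``lags_per_decade`` points
    covering [dt_out, span/2].  Lags exceeding the trajectory span are
    dropped with a warning.
    """
    dt = trajs.dt_out
    n_frames = trajs.x.shape[1]
    span = (n_frames - 1) * dt
    if lags is None:
        lags = np.geomspace(dt, span / 2,
                            max(2, int(np.log10(span / 2 / dt) * lags_per_decade)))
    lags = np.asarray(lags, dtype=float)
    ks = np.unique(np.clip(np.round(lags / dt).astype(int), 1, None))
    if np.any(ks > n_frames - 1):
        warnings.warn("lags beyond the trajectory span were dropped", stacklevel=2)
        ks = ks[ks <= n_frames - 1]
    if len(ks) == 0:
        raise ValueError("no usable lags within the trajectory span")

    x = trajs.x
    vals = np.empty(len(ks))
    errs = np.empty(len(ks))
    n_traj = x.shape[0]
    for i, k in enumerate(ks):
        d = x[:, k:] - x[:, :-k]
        per_traj = np.mean(d * d, axis=1)
        vals[i] = per_traj.mean()
        errs[i] = per_traj.std(ddof=1) / np.sqrt(n_traj) if n_traj > 1 else np.nan
    return MSDCurve(
        lags=ks * dt, values=vals,
        stderr=errs if n_traj > 1 else None,
        meta={**trajs.meta, "provenance": "simulated", "B": trajs.B,
              "n_traj": n_traj},
    )


def alpha_curve(msd: MSDCurve, smooth_window: int = 1) -> AlphaCurve:
    """Log-log slope alpha(t) of an MSD curve by centered differences.

    Three-point centered stencil on the (possibly non-uniform) log grid;
    the endpoints use one-sided stencils and are flagged via
    ``endpoint_mask``.  ``smooth_window`` > 1 applies a moving average over
    that many points afterwards.
    """
    if len(msd.lags) < 3:
        raise ValueError("need at least 3 lags to differentiate")
    if np.any(msd.values <= 0):
        raise ValueError("alpha(t) requires strictly positive MSD values")
    lt = np.log(msd.lags)
    lc = np.log(msd.values)
    alpha = np.gradient(lc, lt)
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        alpha = np.convolve(alpha, kern, mode="same")
    mask = np.zeros(len(alpha), dtype=bool)
    mask[0] = mask[-1] = True
    return AlphaCurve(times=msd.lags.copy(), alpha=alpha,
                      smooth_window=smooth_window, endpoint_mask=mask)


def log_time_average_alpha(a: AlphaCurve, t_lo: float, t_hi: float,
                           n_points: int = 200) -> float:
    """Mean of alpha over exponentially spaced times in [t_lo, t_hi].

    The logarithmic time average smooths the component-wise oscillations of
    alpha(t) for geometric kernels; over [tau_1, tau_n] it recovers the
    closed-form exponent ln(c/d)/ln(c).
    """
    if not (a.times[0] <= t_lo <= t_hi <= a.times[-1]):
        raise ValueError("averaging window must lie within the curve support")
    if t_lo == t_hi:
        return float(np.interp(np.log(t_lo), np.log(a.times), a.alpha))
    ts = np.geomspace(t_lo, t_hi, n_points)
    return float(np.mean(np.interp(np.log(ts), np.log(a.times), a.alpha)))


def _expanding_root(f, lo: float, hi: float, rtol: float = 1e-12) -> float:
    """Root of increasing f with sign change; expands [lo, hi] as needed."""
    for _ in range(200):
        if f(lo) < 0:
            break
        lo /= 8.0
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 8.0
    return float(brentq(f, lo, hi, rtol=rtol, maxiter=300))


def persistence_time(kernel: MemoryKernel, rtol: float = 1e-12) -> float:
    """Self-consistent end of the ballistic regime: root of ``tau G(tau) = 1``.

    ``tau G(tau)`` increases strictly from 0, so the root exists and is
    unique; it satisfies ``tau_p >= tau_m`` with equality in the Markovian
    limit (all memory times << tau_m).
    """
    tau_m = kernel.inertial_time
    f = lambda tau: tau * kernel.integral(tau) - 1.0
    return _expanding_root(f, tau_m, 4.0 * tau_m, rtol=rtol)


def _self_consistent_relaxation(kernel: MemoryKernel, K: float,
                                rtol: float = 1e-12) -> float:
    """Positive root of ``tau = G(tau) / K`` (friction balances restoration).

    Exists iff ``Gamma(0) > K`` (otherwise the restoring force wins at all
    times and no overdamped relaxation scale exists; returns NaN with a
    warning).  Since ``G`` is concave increasing the root is unique.
    """
    if kernel.gamma0 <= K:
        warnings.warn(
            "no positive self-consistent relaxation time: Gamma(0) <= K",
            stacklevel=3,
        )
        return float("nan")
    f = lambda tau: tau * K - kernel.integral(tau)
    guess = 1.0 / (kernel.inertial_time * K)
    return _expanding_root(f, guess, guess, rtol=rtol)


def relaxation_times(kernel: MemoryKernel, potential: Potential,
                     B: float = 1.0) -> TimescaleReport:
    """All derived time scales for a (kernel, potential, B) system.

    Local fields need a potential with an interior minimum; global fields
    need a confining potential; ``tau_D`` is reported for double wells.
    Free potentials yield only ``tau_m``, ``tau_p`` and ``D``.
    """
    tau_m = kernel.inertial_time
    rep = TimescaleReport(
        tau_m=tau_m,
        tau_p=persistence_time(kernel),
        D=B * tau_m,
        B=B,
    )
    try:
        rep.K_loc = local_stiffness(potential)
    except (ValueError, NotImplementedError):
        rep.K_loc = None
    if rep.K_loc is not None:
        rep.tau_rel_loc = 1.0 / (tau_m * rep.K_loc)
        rep.tau_star_loc = _self_consistent_relaxation(kernel, rep.K_loc)
    if getattr(potential, "confining", False):
        rep.K_glob = global_stiffness(potential, B)
        rep.tau_rel_glob = 1.0 / (tau_m * rep.K_glob)
        rep.tau_star_glob = _self_consistent_relaxation(kernel, rep.K_glob)
    if isinstance(potential, DoubleWellPotential):
        rep.tau_D = potential.L**2 / (B * tau_m)
    return rep


@dataclass
class Segment:
    """A labeled stretch of the lag axis with its mean exponent."""

    label: str
    t_lo: float
    t_hi: float
    mean_alpha: float


def regime_classification(msd: MSDCurve, report: TimescaleReport) -> list[Segment]:
    """Partition the lag axis into dynamical regimes.

    Boundaries are the persistence time and the available self-consistent
    relaxation times; segments are labeled ballistic (t < tau_p),
    memory-dominated (tau_p..tau*_loc), barrier+memory (tau*_loc..tau*_glob)
    and confined (t > tau*_glob).  For unconfined systems the post-ballistic
    segment is labeled diffusive when its mean exponent is near 1.
    Overlapping or degenerate boundaries collapse (with a warning) into
    fewer segments; each segment carries the mean alpha inside it.
    """
    a = alpha_curve(msd, smooth_window=min(5, max(1, len(msd.lags) // 10)))
    bounds = [("ballistic", report.tau_p)]
    star_loc = report.tau_star_loc
    star_glob = report.tau_star_glob
    if star_loc is not None and np.isfinite(star_loc):
        bounds.append(("memory-dominated", star_loc))
    if star_glob is not None and np.isfinite(star_glob):
        bounds.append(("barrier+memory", star_glob))
    tail_label = "confined" if star_glob is not None and np.isfinite(star_glob) \
        else ("diffusive" if star_loc is None else "barrier+memory")

    t_lo, t_hi = float(msd.lags[0]), float(msd.lags[-1])
    edges, labels = [t_lo], []
    for label, b in bounds:
        if b <= edges[-1] * 1.001 or b >= t_hi:
            if t_lo < b < t_hi:
                warnings.warn(
                    f"degenerate regime boundary at t={b:g} collapsed",
                    stacklevel=2,
                )
            continue
        edges.append(float(b))
        labels.append(label)
    edges.append(t_hi)
    labels.append(tail_label)

    segments = []
    for i, label in enumerate(labels):
        lo, hi = edges[i], edges[i + 1]
        sel = (a.times >= lo) & (a.times <= hi)
        mean = float(a.alpha[sel].mean()) if np.any(sel) else float("nan")
        segments.append(Segment(label=label, t_lo=lo, t_hi=hi, mean_alpha=mean))
    # relabel an unconfined tail that is actually diffusive
    if segments and segments[-1].label == "diffusive" and segments[-1].mean_alpha < 0.9:
        segments[-1].label = "memory-dominated"
    return segments
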