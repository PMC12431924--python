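"""Multi-exponential friction memory kernels.

The friction kernel of the generalized Langevin equation is represented as a
sum of exponential components,

    Gamma(t) = sum_i (gamma_i / tau_i) exp(-t / tau_i),

with memory times ``tau_i`` and friction amplitudes ``gamma_i``.  In the
mass-free convention used throughout this package every term of the equation
of motion has units of acceleration, so ``Gamma(t)`` carries 1/time**2 and the
amplitudes ``gamma_i`` carry 1/time.  The running friction integral

    G(t) = integral_0^t Gamma(s) ds = sum_i gamma_i (1 - exp(-t / tau_i))

saturates at the total friction ``G(inf) = sum_i gamma_i``, whose reciprocal
is the inertial time ``tau_m`` setting the long-time diffusivity
``D = B * tau_m``.

A geometric family with exponentially spaced times and amplitudes,
``tau_i = tau_1 c**(i-1)`` and ``gamma_i = gamma_1 d**(i-1)``, produces
kernels with an extended power-law window ``Gamma(t) ~ t**(-alpha)`` and a
closed-form subdiffusion exponent ``alpha = ln(c/d)/ln(c)``, valid for
``c >> d > 1`` and ``tau_1 < t < tau_n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "MemoryKernel",
    "GeometricKernelSpec",
    "KernelFitError",
    "expand_geometric",
    "kernel_value",
    "kernel_integral",
    "inertial_time",
    "predict_alpha",
    "fit_power_law",
    "fit_multiexponential",
]


@dataclass(frozen=True)
class MemoryKernel:
    """Friction kernel ``Gamma(t) = sum_i (gamma_i/tau_i) exp(-t/tau_i)``.

    Parameters
    ----------
    taus : array-like
        Memory times ``tau_i`` (time units), strictly positive, sorted
        non-decreasing.  Ties are legal (they add amplitudes of the same
        exponential).
    gammas : array-like
        Friction amplitudes ``gamma_i`` (1/time), strictly positive, ordered
        consistently with ``taus``.
    """

    taus: np.ndarray
    gammas: np.ndarray

    def __post_init__(self) -> None:
        taus = np.atleast_1d(np.asarray(self.taus, dtype=float))
        gammas = np.atleast_1d(np.asarray(self.gammas, dtype=float))
        if taus.ndim != 1 or gammas.ndim != 1 or len(taus) != len(gammas):
            raise ValueError("taus and gammas must be 1-D of equal length")
        if len(taus) < 1:
            raise ValueError("kernel needs at least one component")
        if not (np.all(np.isfinite(taus)) and np.all(np.isfinite(gammas))):
            raise ValueError("kernel parameters must be finite")
        if np.any(taus <= 0) or np.any(gammas <= 0):
            raise ValueError("taus and gammas must be strictly positive")
        if np.any(np.diff(taus) < 0):
            raise ValueError("taus must be sorted in non-decreasing order")
        taus.setflags(write=False)
        gammas.setflags(write=False)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "gammas", gammas)

    @property
    def n(self) -> int:
        """Number of exponential components."""
        return len(self.taus)

    @property
    def total_friction(self) -> float:
        """``G(inf) = sum_i gamma_i`` (1/time)."""
        return float(np.sum(self.gammas))

    @property
    def inertial_time(self) -> float:
        """``tau_m = 1 / sum_i gamma_i`` (time)."""
        return 1.0 / self.total_friction

    @property
    def gamma0(self) -> float:
        """Initial kernel value ``Gamma(0) = sum_i gamma_i / tau_i``."""
        return float(np.sum(self.gammas / self.taus))

    def value(self, t):
        """Evaluate ``Gamma(t)`` (1/time**2) for ``t >= 0`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("kernel is defined for t >= 0 only")
        out = np.sum(
            (self.gammas / self.taus)[:, None]
            * np.exp(-np.atleast_1d(t)[None, :] / self.taus[:, None]),
            axis=0,
        )
        return out.reshape(t.shape) if t.ndim else float(out[0])

    def integral(self, t):
        """Running friction integral ``G(t)`` (1/time); ``t = inf`` allowed."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("G(t) is defined for t >= 0 only")
        ratio = np.atleast_1d(t)[None, :] / self.taus[:, None]
        out = np.sum(self.gammas[:, None] * (-np.expm1(-ratio)), axis=0)
        return out.reshape(t.shape) if t.ndim else float(out[0])

    def laplace(self, s):
        """Laplace transform ``Gamma~(s) = sum_i gamma_i / (1 + tau_i s)``."""
        s = np.asarray(s)
        denom = 1.0 + np.multiply.outer(self.taus, s)
        if np.any(denom == 0):
            raise ZeroDivisionError("s hits a kernel pole at -1/tau_i")
        out = np.sum(self.gammas.reshape((-1,) + (1,) * s.ndim) / denom, axis=0)
        return out if s.ndim else complex(out) if np.iscomplexobj(out) else float(out)

    def coalesced(self) -> "MemoryKernel":
        """Merge components with identical memory times (amplitudes add)."""
        taus, inverse = np.unique(self.taus, return_inverse=True)
        if len(taus) == self.n:
            return self
        gammas = np.zeros_like(taus)
        np.add.at(gammas, inverse, self.gammas)
        return MemoryKernel(taus, gammas)


@dataclass(frozen=True)
class GeometricKernelSpec:
    """Geometric kernel family ``tau_i = tau1*c**(i-1)``, ``gamma_i = gamma1*d**(i-1)``."""

    gamma1: float
    tau1: float
    c: float
    d: float
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("gamma1", "tau1", "c", "d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be an integer >= 1")
        object.__setattr__(self, "n", int(self.n))

    def expand(self) -> MemoryKernel:
        return expand_geometric(self)


def expand_geometric(spec: GeometricKernelSpec) -> MemoryKernel:
    """Expand a geometric family spec into an explicit :class:`MemoryKernel`.

    For ``c < 1`` the generated memory times decrease with the component
    index; components are re-sorted (together with their amplitudes) so the
    kernel invariant (non-decreasing ``taus``) holds.
    """
    i = np.arange(spec.n)
    taus = spec.tau1 * spec.c**i
    gammas = spec.gamma1 * spec.d**i
    order = np.argsort(taus, kind="stable")
    return MemoryKernel(taus[order], gammas[order])


def kernel_value(kernel: MemoryKernel, t):
    """``Gamma(t)``; see :meth:`MemoryKernel.value`."""
    return kernel.value(t)


def kernel_integral(kernel: MemoryKernel, t):
    """``G(t)``; see :meth:`MemoryKernel.integral`."""
    return kernel.integral(t)


def inertial_time(kernel: MemoryKernel) -> float:
    """``tau_m = 1/G(inf)``; sets the long-time diffusivity ``D = B*tau_m``."""
    return kernel.inertial_time


def predict_alpha(c: float, d: float) -> float:
    """Closed-form subdiffusion exponent ``alpha = ln(c/d)/ln(c)``.

    Valid for geometric kernels with ``c >> d > 1`` in the time window
    ``tau_1 < t < tau_n``; a warning (not an error) is emitted outside that
    regime, since the formula itself stays well defined for any ``c > 1``.
    """
    if c <= 0 or d <= 0:
        raise ValueError("c and d must be positive")
    if c == 1:
        raise ValueError("alpha(c, d) is degenerate at c = 1 (ln c = 0)")
    if not (c > d >= 1):
        warnings.warn(
            "alpha(c, d) = ln(c/d)/ln(c) was derived for c >> d > 1; "
            f"got c={c}, d={d}",
            stacklevel=2,
        )
    return 1.0 - np.log(d) / np.log(c)


def fit_power_law(
    kernel: MemoryKernel,
    t_lo: float | None = None,
    t_hi: float | None = None,
    n_points: int = 50,
) -> float:
    """Fit ``Gamma(t) ~ t**(-alpha)`` over a time window; return ``alpha``.

    Least-squares slope of ``ln Gamma`` versus ``ln t`` on ``n_points``
    exponentially spaced points in ``[t_lo, t_hi]`` (default window
    ``[tau_1, tau_n]``), negated.  For a kernel with no genuine power-law
    regime (e.g. a single exponential) the result is window dependent.
    """
    if t_lo is None:
        t_lo = float(kernel.taus[0])
    if t_hi is None:
        t_hi = float(kernel.taus[-1])
    if not (0 < t_lo < t_hi):
        raise ValueError("need 0 < t_lo < t_hi")
    if n_points < 4:
        raise ValueError("need at least 4 points for a stable fit")
    if t_lo < kernel.taus[0] / 10 or t_hi > kernel.taus[-1] * 10:
        warnings.warn(
            "fit window extends well outside the kernel's memory-time support",
            stacklevel=2,
        )
    t = np.geomspace(t_lo, t_hi, n_points)
    g = kernel.value(t)
    if np.any(~np.isfinite(g)) or np.any(g <= 0):
        raise FloatingPointError("kernel underflowed to zero inside the fit window")
    slope = np.polyfit(np.log(t), np.log(g), 1)[0]
    return float(-slope)


class KernelFitError(RuntimeError):
    """Raised when the multi-exponential fit fails to converge.

    Carries the best candidate kernel and its residual norm so the caller can
    inspect (or accept) the non-converged solution.
    """

    def __init__(self, message: str, best: MemoryKernel | None, residual: float):
        super().__init__(message)
        self.best = best
        self.residual = residual


def _fit_amplitudes(t: np.ndarray, g: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Non-negative linear solve for gamma_i at fixed memory times."""
    basis = np.exp(-t[:, None] / taus[None, :]) / taus[None, :]
    amp, _ = nnls(basis, g)
    return amp


def fit_multiexponential(
    t_samples,
    gamma_samples,
    n: int,
    seed: int = 0,
    restarts: int = 10,
    xtol: float = 1e-14,
) -> MemoryKernel:
    """Nonlinear least squares of the multi-exponential kernel to samples.

    Residuals are measured on ``ln Gamma`` so that all decades of the decay
    weigh equally.  Memory times are initialized log-uniformly over the
    sample time range (amplitudes from a non-negative linear solve at fixed
    times), with ``restarts`` seeded random restarts; the best converged
    candidate is returned.  Over-parameterized fits (``n`` larger than the
    number of distinguishable components) are legal and may return duplicate
    time scales.
    """
    t = np.asarray(t_samples, dtype=float)
    g = np.asarray(gamma_samples, dtype=float)
    if t.ndim != 1 or t.shape != g.shape:
        raise ValueError("t_samples and gamma_samples must be 1-D of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_samples must be strictly increasing")
    if np.any(t <= 0) or np.any(g <= 0):
        raise ValueError("samples must be strictly positive")
    if n < 1:
        raise ValueError("n must be >= 1")

    log_t_lo, log_t_hi = np.log(t[0]), np.log(t[-1])
    rng = np.random.default_rng(seed)

    def model_log(params):
        taus = np.exp(params[:n])
        gammas = np.exp(params[n:])
        vals = np.sum(
            (gammas / taus)[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0
        )
        return np.log(np.maximum(vals, 1e-300))

    target = np.log(g)
    best_params, best_cost = None, np.inf
    for trial in range(restarts):
        if trial == 0:
            log_taus = np.linspace(log_t_lo, log_t_hi, n)
        else:
            log_taus = np.sort(rng.uniform(log_t_lo, log_t_hi, n))
        gammas0 = np.maximum(_fit_amplitudes(t, g, np.exp(log_taus)), 1e-12)
        x0 = np.concatenate([log_taus, np.log(gammas0)])
        try:
            res = least_squares(
                lambda p: model_log(p) - target, x0, xtol=xtol, method="lm"
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best_cost, best_params = res.cost, res.x
        if res.success and res.cost < 1e-16 * len(t):
            break

    if best_params is None:
        raise KernelFitError("multi-exponential fit failed on all restarts", None, np.inf)
    taus = np.exp(best_params[:n])
    gammas = np.exp(best_params[n:])
    order = np.argsort(taus)
    kernel = MemoryKernel(taus[order], gammas[order])
    residual = float(np.sqrt(2 * best_cost / len(t)))
    if not np.isfinite(residual):
        raise KernelFitError("multi-exponential fit produced non-finite residual",
                             kernel, residual)
    return kernel
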