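"""1-D potential landscapes (per unit mass) and their Boltzmann statistics.

Potentials enter the equation of motion through the force ``-U'(x)`` and are
expressed per unit mass, so ``U`` carries length**2/time**2 and thermal energy
is measured by the velocity variance ``B = <xdot**2>`` (``k_B T / m`` in the
equipartition convention).

Available landscapes:

* ``free`` — ``U = 0``.
* ``harmonic`` — ``U = K x**2 / 2`` with stiffness ``K`` (1/time**2).
* ``double_well`` — ``U = U0 ((x/L)**2 - 1)**2``: symmetric wells at
  ``x = +-L`` separated by a barrier of height ``U0`` at ``x = 0``; curvature
  at the minima is ``K_loc = 8 U0 / L**2``.
* ``tabulated`` — cubic-spline interpolation of an (x, U) table, e.g. a
  protein folding free-energy profile along a reaction coordinate.

Two harmonic surrogates of an anharmonic well are used throughout: the
*local* stiffness (curvature at the minimum) and the *global* stiffness
``K_glob = B / <x**2>`` matching the Boltzmann positional variance.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy.integrate import IntegrationWarning, quad
from scipy.interpolate import CubicSpline

__all__ = [
    "Potential",
    "FreePotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "TabulatedPotential",
    "potential_value",
    "local_stiffness",
    "boltzmann_variance",
    "global_stiffness",
    "boltzmann_sample",
]

# Boltzmann-weight truncation: mass beyond U - Umin > _CUTOFF*B is < e^-50.
_CUTOFF = 50.0


class Potential(ABC):
    """Contract: value, slope and curvature on the queried domain."""

    kind: str
    confining: bool

    @abstractmethod
    def value(self, x):
        """Potential ``U(x)`` (length**2/time**2)."""

    @abstractmethod
    def grad(self, x):
        """Slope ``U'(x)``; the force is ``-U'(x)``."""

    @abstractmethod
    def curvature(self, x):
        """Second derivative ``U''(x)`` (1/time**2)."""

    def support(self, B: float) -> tuple[float, float]:
        """Interval containing all but ~e^-50 of the Boltzmann mass."""
        raise NotImplementedError


@dataclass(frozen=True)
class FreePotential(Potential):
    kind = "free"
    confining = False

    def value(self, x):
        return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0

    grad = value
    curvature = value


@dataclass(frozen=True)
class HarmonicPotential(Potential):
    """``U(x) = K x**2 / 2``."""

    K: float
    kind = "harmonic"
    confining = True

    def __post_init__(self):
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError("harmonic stiffness K must be positive")

    def value(self, x):
        return 0.5 * self.K * np.asarray(x, dtype=float) ** 2

    def grad(self, x):
        return self.K * np.asarray(x, dtype=float)

    def curvature(self, x):
        x = np.asarray(x, dtype=float)
        return np.full_like(x, self.K) if x.ndim else self.K

    def support(self, B):
        half = np.sqrt(2 * _CUTOFF * B / self.K)
        return (-half, half)


@dataclass(frozen=True)
class DoubleWellPotential(Potential):
    """``U(x) = U0 ((x/L)**2 - 1)**2``.

    Minima at ``x = +-L`` (``U = 0``), barrier top at ``x = 0`` (``U = U0``),
    curvature at the minima ``8 U0 / L**2``.  ``U0 = 0`` degenerates to the
    free potential and is therefore not confining.
    """

    U0: float
    L: float
    kind = "double_well"

    def __post_init__(self):
        if not (np.isfinite(self.U0) and self.U0 >= 0):
            raise ValueError("barrier height U0 must be >= 0")
        if not (np.isfinite(self.L) and self.L > 0):
            raise ValueError("well distance L must be positive")

    @property
    def confining(self) -> bool:
        return self.U0 > 0

    def value(self, x):
        u = (np.asarray(x, dtype=float) / self.L) ** 2 - 1.0
        return self.U0 * u * u

    def grad(self, x):
        x = np.asarray(x, dtype=float)
        return 4.0 * self.U0 * x * ((x / self.L) ** 2 - 1.0) / self.L**2

    def curvature(self, x):
        x = np.asarray(x, dtype=float)
        return 4.0 * self.U0 * (3.0 * x**2 / self.L**2 - 1.0) / self.L**2

    def support(self, B):
        # solve U0 ((x/L)^2 - 1)^2 = cutoff*B outward of the minima
        half = self.L * np.sqrt(1.0 + np.sqrt(_CUTOFF * B / self.U0))
        return (-half, half)


class TabulatedPotential(Potential):
    """Cubic-spline interpolation of a sampled landscape.

    Natural boundary conditions keep ``U''`` well behaved at the edges;
    queries outside the tabulated range raise rather than extrapolate.
    The Boltzmann weight is supported on the tabulated interval only, so a
    tabulated potential is treated as confining on its own domain.
    """

    kind = "tabulated"
    confining = True

    def __init__(self, x, U):
        x = np.asarray(x, dtype=float)
        U = np.asarray(U, dtype=float)
        if x.ndim != 1 or x.shape != U.shape or len(x) < 4:
            raise ValueError("need matching 1-D grids with at least 4 nodes")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x grid must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(U))):
            raise ValueError("grids must be finite")
        self.x = x
        self.U = U
        self._spline = CubicSpline(x, U, bc_type="natural")

    def _check(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x[0]) or np.any(x > self.x[-1]):
            raise ValueError("query outside the tabulated range")
        return x

    def value(self, x):
        out = self._spline(self._check(x))
        return out if np.ndim(x) else float(out)

    def grad(self, x):
        out = self._spline(self._check(x), 1)
        return out if np.ndim(x) else float(out)

    def curvature(self, x):
        out = self._spline(self._check(x), 2)
        return out if np.ndim(x) else float(out)

    def support(self, B):
        return (float(self.x[0]), float(self.x[-1]))


def potential_value(p: Potential, x):
    """``U(x)``; see :meth:`Potential.value`."""
    return p.value(x)


def _minimum(p: Potential) -> float:
    """Location of the deepest interior minimum."""
    if isinstance(p, HarmonicPotential):
        return 0.0
    if isinstance(p, DoubleWellPotential):
        if p.U0 == 0:
            raise ValueError("flat potential (U0 = 0) has no local minimum")
        return p.L
    if isinstance(p, TabulatedPotential):
        xs = np.linspace(p.x[0], p.x[-1], 4 * len(p.x))
        us = p.value(xs)
        interior = (
            (np.r_[True, us[1:] <= us[:-1]]) & (np.r_[us[:-1] <= us[1:], True])
        )
        interior[0] = interior[-1] = False
        if not np.any(interior):
            raise ValueError("tabulated potential has no interior minimum")
        x0 = xs[interior][np.argmin(us[interior])]
        # Newton-polish on the spline
        for _ in range(50):
            g, c = p.grad(x0), p.curvature(x0)
            if c <= 0:
                break
            step = g / c
            x1 = np.clip(x0 - step, p.x[0], p.x[-1])
            if abs(x1 - x0) < 1e-14 * (p.x[-1] - p.x[0]):
                x0 = x1
                break
            x0 = x1
        return float(x0)
    raise ValueError(f"no local minimum defined for kind {p.kind!r}")


def local_stiffness(p: Potential) -> float:
    """Curvature ``U''`` at the (deepest) local minimum, ``K_loc``.

    For the double well this equals ``8 U0 / L**2`` analytically; for a
    harmonic potential it is ``K`` itself.
    """
    k = float(p.curvature(_minimum(p)))
    if k <= 0:
        raise ValueError("curvature at the located minimum is not positive")
    return k


def _require_confining(p: Potential):
    if not getattr(p, "confining", False):
        raise ValueError(
            f"potential of kind {p.kind!r} is not confining; "
            "Boltzmann statistics are undefined"
        )


def _boltzmann_moments(p: Potential, B: float) -> tuple[float, float, float]:
    """(Z, <x>, <x^2>) over the truncated support by adaptive quadrature."""
    _require_confining(p)
    if B <= 0:
        raise ValueError("B must be positive")
    lo, hi = p.support(B)
    umin = float(np.min(p.value(np.linspace(lo, hi, 2049))))
    w = lambda x: np.exp(-(p.value(x) - umin) / B)
    pts = [0.5 * (lo + hi)]
    if isinstance(p, DoubleWellPotential):
        pts = [-p.L, 0.0, p.L]
    kw = dict(epsabs=0.0, epsrel=1e-12, limit=400, points=pts)
    with warnings.catch_warnings():
        # pure-relative 1e-12 tolerance can trip QUADPACK's roundoff
        # heuristic near machine precision; accuracy is oracle-checked
        warnings.simplefilter("ignore", IntegrationWarning)
        z, _ = quad(w, lo, hi, **kw)
        if isinstance(p, (HarmonicPotential, DoubleWellPotential)):
            m1 = 0.0  # symmetric by construction
        else:
            m1, _ = quad(lambda x: x * w(x), lo, hi, limit=400, points=pts,
                         epsrel=1e-12, epsabs=1e-12 * z * max(abs(lo), abs(hi)))
        m2, _ = quad(lambda x: x * x * w(x), lo, hi, **kw)
    if not (np.isfinite(z) and z > 0 and np.isfinite(m2)):
        raise FloatingPointError("Boltzmann quadrature did not converge")
    return z, m1 / z, m2 / z


def boltzmann_variance(p: Potential, B: float) -> float:
    """Equilibrium positional variance ``<x**2> - <x>**2`` at temperature ``B``.

    For symmetric potentials the mean vanishes and this is the plain second
    moment ``integral x**2 e^{-U/B} dx / integral e^{-U/B} dx``.  Computed by
    adaptive quadrature on the support where ``U - Umin <= 50 B`` (the
    excluded tail carries < e^-50 relative mass).
    """
    _, mean, m2 = _boltzmann_moments(p, B)
    return float(m2 - mean * mean)


def global_stiffness(p: Potential, B: float) -> float:
    """Effective harmonic stiffness ``K_glob = B / <x**2>``.

    The harmonic potential with this stiffness has the same Boltzmann
    positional variance as ``p``; it captures the global confinement a
    bounded landscape exerts at long times.
    """
    return B / boltzmann_variance(p, B)


def boltzmann_sample(p: Potential, B: float, count: int, seed: int) -> np.ndarray:
    """Draw i.i.d. positions with density proportional to ``e^{-U(x)/B}``.

    Deterministic inverse-CDF sampling on a 2**14-point grid over the
    truncated support; the grid CDF is piecewise-linearly inverted, which is
    exact to the grid resolution and bit-reproducible for a fixed seed.
    """
    _require_confining(p)
    if count < 1:
        raise ValueError("count must be >= 1")
    lo, hi = p.support(B)
    grid = np.linspace(lo, hi, 2**14)
    u = p.value(grid)
    dens = np.exp(-(u - np.min(u)) / B)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    # strictly increasing knots for interpolation
    keep = np.r_[True, np.diff(cdf) > 0]
    rng = np.random.default_rng(seed)
    return np.interp(rng.random(count), cdf[keep], grid[keep])
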