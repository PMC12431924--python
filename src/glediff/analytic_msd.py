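"""Exact MSD of the GLE with multi-exponential memory, free or harmonically confined.

For the mass-free GLE with kernel ``Gamma(t)`` and harmonic potential
``U = K x**2 / 2`` the position autocorrelation has the Laplace transform

    Cxx~(s) = (B/K) (s + Gamma~(s)) / (s**2 + s Gamma~(s) + K),

with ``Gamma~(s) = sum_i gamma_i / (1 + tau_i s)``, and the MSD follows from
``C_MSD(t) = 2 B/K - 2 Cxx(t)``.  For free diffusion (``K = 0``)

    C_MSD~(s) = 2 B / (s**2 (s + Gamma~(s))).

Multiplying through by ``prod_i (1 + tau_i s)`` turns both transforms into
rational functions; with

    Q(s) = s prod_i (1 + tau_i s) + sum_i gamma_i prod_{j != i} (1 + tau_j s)
    P(s) = s Q(s) + K prod_i (1 + tau_i s)

the poles are the roots of ``P`` (degree n+2) for ``K > 0``, or the roots of
``Q`` (degree n+1) plus a double pole at ``s = 0`` for ``K = 0``.  Partial
fractions then give the MSD exactly as a constant, an optional linear term
(``2 B tau_m t``, free case only) and a sum of exponential modes.

Geometric kernels span time-scale ratios of 1e16 and more, which makes the
assembled polynomials severely ill-conditioned in double precision.  All
root finding, residue extraction and curve evaluation therefore run in
mpmath arbitrary precision, with the working precision scaled to the
kernel's dynamic range; results are returned as float arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np

from .kernels import MemoryKernel

__all__ = [
    "ModeDecomposition",
    "laplace_kernel",
    "characteristic_roots",
    "msd_mode_decomposition",
    "evaluate_msd",
    "analytic_msd",
]


def laplace_kernel(kernel: MemoryKernel, s):
    """``Gamma~(s) = sum_i gamma_i / (1 + tau_i s)``; ``Gamma~(0) = 1/tau_m``."""
    return kernel.laplace(s)


def _working_dps(kernel: MemoryKernel, K: float) -> int:
    """Decimal digits needed for the kernel's time-scale dynamic range."""
    spread = math.log10(kernel.taus[-1] / kernel.taus[0]) if kernel.n > 1 else 0.0
    spread += abs(math.log10(kernel.gammas.max() / kernel.gammas.min())) if kernel.n > 1 else 0.0
    scale = abs(math.log10(kernel.taus[-1])) + abs(math.log10(kernel.taus[0]))
    return int(50 + 2.5 * spread + scale)


def _poly_mul(a: list, b: list) -> list:
    """Product of polynomials given by ascending coefficient lists."""
    out = [mp.mpf(0)] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


def _poly_add(a: list, b: list) -> list:
    n = max(len(a), len(b))
    a = a + [mp.mpf(0)] * (n - len(a))
    b = b + [mp.mpf(0)] * (n - len(b))
    return [x + y for x, y in zip(a, b)]


def _assemble(kernel: MemoryKernel, K: float):
    """Ascending-coefficient lists for N(s)=prod(1+tau_i s), Q(s), P(s)."""
    k = kernel.coalesced()
    taus = [mp.mpf(t) for t in k.taus]
    gammas = [mp.mpf(g) for g in k.gammas]
    N = [mp.mpf(1)]
    for t in taus:
        N = _poly_mul(N, [mp.mpf(1), t])
    Q = [mp.mpf(0)] + N  # s * N(s)
    for i, g in enumerate(gammas):
        part = [mp.mpf(1)]
        for j, t in enumerate(taus):
            if j != i:
                part = _poly_mul(part, [mp.mpf(1), t])
        Q = _poly_add(Q, [g * c for c in part])
    P = _poly_add([mp.mpf(0)] + Q, [mp.mpf(K) * c for c in N])
    return N, Q, P


def _poly_eval(coeffs: list, s):
    acc = mp.mpf(0)
    for c in reversed(coeffs):
        acc = acc * s + c
    return acc


def _poly_deriv(coeffs: list) -> list:
    return [i * c for i, c in enumerate(coeffs)][1:]


def _roots(coeffs: list):
    """All roots of an ascending-coefficient polynomial, Newton-polished."""
    asc = list(coeffs)
    while asc and asc[-1] == 0:
        asc = asc[:-1]
    roots = mp.polyroots(asc, maxsteps=200, extraprec=2 * mp.mp.prec, asc=True)
    dcoeffs = _poly_deriv(coeffs)
    polished = []
    for r in roots:
        z = mp.mpc(r)
        for _ in range(8):
            f = _poly_eval(coeffs, z)
            df = _poly_eval(dcoeffs, z)
            if df == 0:
                break
            step = f / df
            z -= step
            if abs(step) <= mp.mpf(10) ** (-mp.mp.dps + 5) * max(abs(z), mp.mpf(1)):
                break
        polished.append(z)
    return polished


def _cluster(roots, rel_gap: float = 1e-9):
    """Group numerically coincident roots (merged higher-order poles)."""
    remaining = list(roots)
    clusters = []
    while remaining:
        r = remaining.pop(0)
        members = [r]
        keep = []
        for other in remaining:
            scale = max(abs(r), abs(other), mp.mpf(1e-300))
            if abs(r - other) / scale < rel_gap:
                members.append(other)
            else:
                keep.append(other)
        remaining = keep
        center = sum(members) / len(members)
        clusters.append((center, len(members)))
    return clusters


@dataclass
class ModeDecomposition:
    """Exponential-mode representation of the analytic MSD.

    ``C(t) = offset + linear_coeff * t
           + Re sum_k (sum_m residues[k][m] t**m) exp(rates[k] t)``

    Almost every pole is simple, so ``residues[k]`` is usually the single
    coefficient ``[a_k]``; numerically coincident poles are merged into one
    higher-order entry.  Complex rates occur in conjugate pairs and the
    assembled curve is real.  For ``K > 0`` the offset is the plateau
    ``2 B / K`` and the linear term vanishes; for ``K = 0`` the linear
    coefficient is ``2 B tau_m`` (long-time diffusivity ``D = B tau_m``).

    High-precision (mpmath) copies of the rates/residues are retained and
    used for evaluation: near ``t = 0`` the constant, linear and exponential
    parts cancel to ``O(B t**2)``, which double precision cannot resolve over
    the parameter ranges of interest.
    """

    rates: np.ndarray
    residues: list  # list of complex-coefficient lists, residues[k][m] ~ t**m
    linear_coeff: float
    offset: float
    B: float
    K: float
    dps: int
    _mp_rates: list = field(repr=False, default_factory=list)
    _mp_residues: list = field(repr=False, default_factory=list)
    _mp_linear: object = field(repr=False, default=None)
    _mp_offset: object = field(repr=False, default=None)


def characteristic_roots(kernel: MemoryKernel, K: float = 0.0):
    """Decay rates of the MSD modes: roots of ``P`` (K>0) or ``Q`` (K=0).

    The trivial double root at ``s = 0`` of the free-case MSD transform is
    excluded (it produces the constant + linear terms).  All returned rates
    have negative real part for ``K >= 0`` and any valid kernel.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    with mp.workdps(_working_dps(kernel, K)):
        _, Q, P = _assemble(kernel, K)
        roots = _roots(P if K > 0 else Q)
        return np.array([complex(r) for r in roots])


def msd_mode_decomposition(
    kernel: MemoryKernel, K: float = 0.0, B: float = 1.0
) -> ModeDecomposition:
    """Partial-fraction expansion of the analytic MSD.

    See the module docstring for the rational functions being expanded.
    Residues at a simple pole ``s_k`` of ``num(s)/den(s)`` are
    ``num(s_k)/den'(s_k)``; numerically coincident poles (relative gap below
    1e-9, e.g. deliberately degenerate kernels) are merged and their residue
    polynomial extracted from a local Taylor expansion.
    """
    if K < 0 or B <= 0:
        raise ValueError("need K >= 0 and B > 0")
    dps = _working_dps(kernel, K)
    with mp.workdps(dps):
        N, Q, P = _assemble(kernel, K)
        mpB = mp.mpf(B)
        if K > 0:
            den = P
            # C_MSD(t) = 2B/K - 2 Cxx(t), Cxx~ = (B/K) Q(s)/P(s)
            num = [-2 * (mpB / mp.mpf(K)) * c for c in Q]
            offset = 2 * mpB / mp.mpf(K)
            linear = mp.mpf(0)
        else:
            den = Q
            # C_MSD~ = 2B N(s) / (s^2 Q(s)); the s=0 double pole gives
            # linear = 2B N(0)/Q(0) = 2B tau_m and
            # offset = 2B d/ds[N/Q](0).
            num = [2 * mpB * c for c in N]
            Q0, Qp0 = Q[0], Q[1]
            N0, Np0 = N[0], N[1]
            linear = 2 * mpB * N0 / Q0
            offset = 2 * mpB * (Np0 * Q0 - N0 * Qp0) / (Q0 * Q0)

        roots = _roots(den)
        lead = den[-1]
        clusters = _cluster(roots)
        rates, residues = [], []
        for center, mult in clusters:
            others = []
            for c2, m2 in clusters:
                if c2 is not center:
                    others.extend([c2] * m2)

            def g(s, _others=others):
                val = _poly_eval(num, s) / lead
                for o in _others:
                    val /= s - o
                if K == 0:
                    val /= s * s
                return val

            if mult == 1:
                coeffs = [g(center)]
            else:
                taylor = mp.taylor(g, center, mult - 1)
                # (sum_j c_j (s-s0)^j)/(s-s0)^mult inverts to
                # sum_m [c_{mult-1-m} / m!] t^m e^{s0 t}
                coeffs = [taylor[mult - 1 - m] / mp.factorial(m) for m in range(mult)]
            rates.append(center)
            residues.append(coeffs)

        decomp = ModeDecomposition(
            rates=np.array([complex(r) for r in rates]),
            residues=[[complex(c) for c in coeffs] for coeffs in residues],
            linear_coeff=float(linear),
            offset=float(offset),
            B=float(B),
            K=float(K),
            dps=dps,
            _mp_rates=rates,
            _mp_residues=residues,
            _mp_linear=linear,
            _mp_offset=offset,
        )
        _validate(decomp)
        return decomp


def _msd_mp(decomp: ModeDecomposition, t):
    """High-precision MSD at scalar time t (within an mp.workdps block)."""
    acc = decomp._mp_offset + decomp._mp_linear * t
    for rate, coeffs in zip(decomp._mp_rates, decomp._mp_residues):
        poly = mp.mpf(0)
        for m, c in enumerate(coeffs):
            poly += c * mp.power(t, m) if m else c
        acc += poly * mp.exp(rate * t)
    return acc


def _validate(decomp: ModeDecomposition) -> None:
    if np.any(decomp.rates.real >= 0):
        raise FloatingPointError(
            "unstable mode detected (Re s >= 0); kernel/K input is outside "
            "the stable regime or precision was insufficient"
        )
    scale = abs(decomp.offset) + abs(decomp.linear_coeff) * (
        1.0 / abs(decomp.rates.real).min()
    )
    c0 = _msd_mp(decomp, mp.mpf(0))
    if abs(complex(c0)) > 1e-10 * max(scale, 1e-300):
        raise FloatingPointError("assembled MSD does not vanish at t = 0")


def evaluate_msd(decomp: ModeDecomposition, times) -> np.ndarray:
    """Evaluate the analytic MSD on a positive time grid (float array out).

    Evaluation runs at the decomposition's working precision; the imaginary
    residue of the conjugate-pair sum is checked to be below 1e-12 relative.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    out = np.empty(t.shape)
    with mp.workdps(decomp.dps):
        for i, ti in enumerate(t):
            val = _msd_mp(decomp, mp.mpf(ti))
            re, im = mp.re(val), mp.im(val)
            if abs(im) > 1e-12 * max(abs(re), mp.mpf(1e-300)):
                raise FloatingPointError(
                    f"non-real MSD value at t={ti}: conjugate symmetry broken"
                )
            out[i] = float(re)
    if np.any(out < -1e-12 * max(abs(out).max(), 1e-300)):
        raise FloatingPointError("negative MSD value: precision exhausted")
    out = np.maximum(out, 0.0)
    return out if np.ndim(times) else float(out[0])


def analytic_msd(
    kernel: MemoryKernel,
    K: float = 0.0,
    B: float = 1.0,
    t_min: float = None,
    t_max: float = None,
    points_per_decade: int = 16,
):
    """Convenience: mode decomposition + log-grid evaluation in one call.

    Returns an :class:`~glediff.msd_analysis.MSDCurve` on a log-spaced lag
    grid.  Defaults span from three decades below the shortest memory time
    to three decades above the longest (or the harmonic relaxation time if
    that is longer).
    """
    from .msd_analysis import MSDCurve

    if t_min is None:
        t_min = 1e-3 * float(min(kernel.taus[0], kernel.inertial_time))
    if t_max is None:
        t_max = 1e3 * float(kernel.taus[-1])
        if K > 0:
            t_max = max(t_max, 1e3 / (kernel.inertial_time * K))
    n_pts = max(2, int(round(np.log10(t_max / t_min) * points_per_decade)))
    lags = np.geomspace(t_min, t_max, n_pts)
    decomp = msd_mode_decomposition(kernel, K=K, B=B)
    values = evaluate_msd(decomp, lags)
    return MSDCurve(
        lags=lags,
        values=values,
        stderr=None,
        meta={"provenance": "analytic", "B": B, "K": K,
              "taus": kernel.taus.tolist(), "gammas": kernel.gammas.tolist()},
    )
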