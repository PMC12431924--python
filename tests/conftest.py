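import mpmath as mp
import numpy as np
import pytest

from glediff import (
    DoubleWellPotential,
    GeometricKernelSpec,
    HarmonicPotential,
    MemoryKernel,
    expand_geometric,
)


@pytest.fixture
def three_comp():
    """3-component kernel with a decade of spread; tau_m = 1/7."""
    return MemoryKernel([0.1, 1.0, 10.0], [1.0, 2.0, 4.0])


@pytest.fixture
def double_well():
    return DoubleWellPotential(U0=4.0, L=1.0)


@pytest.fixture
def harmonic():
    return HarmonicPotential(K=1.0)


def make_random_kernel(rng: np.random.Generator) -> MemoryKernel:
    """Random multi-exponential kernel with moderate spreads (1-5 components)."""
    n = int(rng.integers(1, 6))
    tau1 = 10.0 ** rng.uniform(-3, 0)
    ratios = 10.0 ** rng.uniform(0.3, 1.7, n - 1)
    taus = tau1 * np.concatenate([[1.0], np.cumprod(ratios)])
    gammas = 10.0 ** rng.uniform(-1, 1, n)
    return MemoryKernel(taus, gammas)


def geometric_unit_tau_m(c: float, d: float, n: int) -> MemoryKernel:
    """Geometric kernel with tau_1 = tau_m = 1 (amplitudes normalized)."""
    gamma1 = 1.0 / sum(d**i for i in range(n))
    return expand_geometric(
        GeometricKernelSpec(gamma1=gamma1, tau1=1.0, c=c, d=d, n=n)
    )


def geometric_overdamped(c: float, d: float, n: int) -> MemoryKernel:
    """Geometric kernel overdamped at its shortest memory time
    (gamma_1 = 1/tau_1 = 1), so the subdiffusive window spans
    [tau_1, tau_n] and the log-averaged exponent there follows
    ln(c/d)/ln(c)."""
    return expand_geometric(GeometricKernelSpec(1.0, 1.0, c, d, n))


def msd_laplace_transform(kernel: MemoryKernel, K: float, B: float):
    """Laplace transform of the MSD, written independently of the package's
    polynomial/partial-fraction machinery, for use with mpmath.invertlaplace."""

    gammas = [mp.mpf(g) for g in kernel.gammas]
    taus = [mp.mpf(t) for t in kernel.taus]
    mpB, mpK = mp.mpf(B), mp.mpf(K)

    def f(s):
        G = sum(g / (1 + t * s) for g, t in zip(gammas, taus))
        if K > 0:
            cxx = (mpB / mpK) * (s + G) / (s * s + s * G + mpK)
            return 2 * mpB / mpK / s - 2 * cxx
        return 2 * mpB / (s * s * (s + G))

    return f


def loglog_slope(decomp, t: float, h: float = 10**0.005) -> float:
    """Centered log-log slope of the analytic MSD at time t."""
    from glediff import evaluate_msd

    lo, hi = evaluate_msd(decomp, np.array([t / h, t * h]))
    return float((np.log(hi) - np.log(lo)) / (2 * np.log(h)))
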