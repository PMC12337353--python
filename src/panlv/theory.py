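"""Closed-form predictions the simulator is tested against.

Effective temperatures of the Gamma abundance ensembles, persistence
criteria from the shape of the abundance PDF, the resulting critical
transfer rates and diversity carrying capacities, and the mean-field
Lyapunov drift.  Prefactors of the critical rates are order one and
configurable; defaults are 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TheoryPrediction",
    "gamma_pdf",
    "predicted_temperatures",
    "extinction_criteria",
    "critical_hgt_rates",
    "max_diversity",
    "min_interbacteria_rate",
    "mean_field_drift",
    "invert_genotype_count",
    "predict",
]


def gamma_pdf(n, n_star: float, theta: float):
    """Gamma density with mean ``n_star`` and scale ``theta``.

    The shape parameter is ``n_star / theta``; at ``theta = n_star`` this is
    the exponential distribution with mean ``n_star``.
    """
    n = np.asarray(n, dtype=float)
    if n_star <= 0 or theta <= 0:
        raise ValueError("n_star and theta must be positive")
    if (n <= 0).any():
        raise ValueError("abundance must be positive")
    out = stats.gamma.pdf(n, a=n_star / theta, scale=theta)
    return float(out) if out.ndim == 0 else out


def predicted_temperatures(r: float, regime: str) -> tuple[float, float]:
    """Effective temperatures (Theta for genotypes, theta for genes).

    Regime II (boom-bust): ``Theta = theta = 1/(2r)``.
    Regime III (stochastic oscillations): ``Theta = 1/(2r)``, ``theta = 2/r``
    (gene-level fluctuations amplified by abundance-biased transfer).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if regime == "II":
        return 1.0 / (2.0 * r), 1.0 / (2.0 * r)
    if regime == "III":
        return 1.0 / (2.0 * r), 2.0 / r
    raise ValueError(f"regime must be 'II' or 'III', got {regime!r}")


def extinction_criteria(
    N: float, K: float, L: float, Theta: float, theta: float
) -> tuple[float, float]:
    """Shape margins of the genotype and gene abundance PDFs.

    Returns ``(N/(K*Theta) - 1, 2N/(L*theta) - 1)``.  A positive margin
    means the Gamma shape parameter exceeds one, the PDF mode is interior,
    and the genotype (resp. gene) persists; at zero the mode reaches the
    origin and extinction sets in.
    """
    if min(N, K, L, Theta, theta) <= 0:
        raise ValueError("all arguments must be positive")
    return N / (K * Theta) - 1.0, 2.0 * N / (L * theta) - 1.0


def critical_hgt_rates(
    L: float, K: float, N: float, c_g: float = 1.0, c_G: float = 1.0
) -> tuple[float, float]:
    """Minimal per-capita transfer rates for gene and genotype maintenance.

    ``rcg = c_g * L / N`` and ``rcG = c_G * K / N`` with order-1 prefactors.
    """
    if min(L, K, N) <= 0:
        raise ValueError("L, K, N must be positive")
    return c_g * L / N, c_G * K / N


def max_diversity(
    r: float, N: float, c_g: float = 1.0, c_G: float = 1.0
) -> tuple[float, float]:
    """Diversity carrying capacities ``Lmax = rN/c_g`` and ``Kmax = rN/c_G``."""
    if r <= 0 or N <= 0:
        raise ValueError("r and N must be positive")
    return r * N / c_g, r * N / c_G


def invert_genotype_count(K: float, g: int = 2) -> float:
    """Gene-pool size whose genotype count is ``K`` (``binomial(L, g) = K``)."""
    if K <= 0:
        raise ValueError("K must be positive")
    if g == 2:
        return (1.0 + math.sqrt(1.0 + 8.0 * K)) / 2.0
    if g == 3:
        # solve L(L-1)(L-2) = 6K by Newton from the cube-root estimate
        L = (6.0 * K) ** (1.0 / 3.0) + 1.0
        for _ in range(50):
            f = L * (L - 1) * (L - 2) - 6.0 * K
            df = 3 * L * L - 6 * L + 2
            L -= f / df
        return L
    raise ValueError("g must be 2 or 3")


def min_interbacteria_rate(L: float, NB: float) -> float:
    """Minimal inter-bacteria transfer rate ``L / NB`` at saturating phage-side
    transfer (the I/II boundary for ``rB``)."""
    if L <= 0 or NB <= 0:
        raise ValueError("L and NB must be positive")
    return L / NB


def mean_field_drift(
    B: float, V: float, n_star: float, r: float, N: float, K: float
) -> tuple[float, float]:
    """Mean-field drift and noise scale of the Lyapunov energy of one pair.

    ``drift = n*^2/(2B) + n*^2/(2V) - (rN/K) * [(n*-B)/B + (n*-V)/V]``;
    ``diffusion_scale = sqrt((B-n*)^2/B + (V-n*)^2/V)``.  Demographic noise
    contributes a positive drift (energy grows); the transfer term is
    restoring (nonpositive) whenever both abundances are below ``n*``.
    Treated as a qualitative contract (sign structure, fixed-point value).
    """
    if B <= 0 or V <= 0 or n_star <= 0:
        raise ValueError("abundances must be positive")
    noise = n_star**2 / (2.0 * B) + n_star**2 / (2.0 * V)
    hgt = -(r * N / K) * ((n_star - B) / B + (n_star - V) / V)
    diffusion = math.sqrt((B - n_star) ** 2 / B + (V - n_star) ** 2 / V)
    return noise + hgt, diffusion


@dataclass
class TheoryPrediction:
    """Bundle of closed-form predictions for one parameter point."""

    Theta_pred: float
    theta_pred: float
    rcg: float
    rcG: float
    Lmax: float
    Kmax: float
    c_g: float
    c_G: float
    tau_boom: float
    n_boom: float


def predict(
    L: float,
    K: float,
    N: float,
    r: float,
    regime: str = "III",
    c_g: float = 1.0,
    c_G: float = 1.0,
    s: float = 5e-3,
) -> TheoryPrediction:
    """Evaluate all closed-form predictions at one parameter point.

    ``tau_boom = log(s N / L) / s`` is the growth period of a booming
    clone and ``n_boom = r N`` the expected number of concurrent booms.
    """
    Theta, theta = predicted_temperatures(r, regime)
    rcg, rcG = critical_hgt_rates(L, K, N, c_g, c_G)
    Lmax, Kmax = max_diversity(r, N, c_g, c_G)
    return TheoryPrediction(
        Theta_pred=Theta,
        theta_pred=theta,
        rcg=rcg,
        rcG=rcG,
        Lmax=Lmax,
        Kmax=Kmax,
        c_g=c_g,
        c_G=c_G,
        tau_boom=math.log(max(s * N / L, math.e)) / s,
        n_boom=r * N,
    )
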