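"""Expected lifespan of recombination-hotspot target motifs.

Biased gene conversion against an active hotspot motif behaves like genic
selection of scaled intensity ``G = 4*Ne*g`` in favor of motif-disrupting
alleles.  Under the approximation that each new disrupting mutation is
immediately either lost or fixed, the per-generation substitution rate at a
motif of ``k`` disruptible sites is ``mu*k`` times the fixation-rate
inflation ``G / (1 - exp(-G))`` relative to neutrality, so the probability
that the motif carries at least one disrupting substitution after ``T``
generations is

    P(G) = 1 - exp(-mu * k * T * G / (1 - exp(-G)))

with the neutral limit ``1 - exp(-mu*k*T)``.  Averaging P over a gamma
distribution of G (induced by the variation of local crossover rates)
yields genome-wide loss predictions; conditioning the average on an upper
quantile range gives predictions for the most recombinogenic motifs.

The module also provides the diffusion fixation probability and the
conditional mean fixation time of a new semidominant mutant under the same
``G`` scaling used everywhere in this package (drift coefficient
``G*x*(1-x)/(4N)``), both validated against the forward Wright-Fisher
simulator in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .sfs import GDistribution

__all__ = [
    "LifespanParams",
    "loss_probability",
    "expected_loss_fraction",
    "calibrate_tail_mean",
    "kimura_fixation_probability",
    "kimura_mean_fixation_time",
]


@dataclass
class LifespanParams:
    """Parameters of the motif-loss clock.

    mu : mutation rate per bp per generation (human pedigree estimate).
    k  : number of disruptible motif positions (11 for the 13-bp hotspot
         motif once its two N positions are removed).
    T  : horizon in generations.
    N  : diploid effective population size (used by the diffusion helpers).
    """

    mu: float = 1.2e-8
    k: int = 11
    T: float = 1e5
    N: int = 10_000

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.k <= 0 or self.T <= 0:
            raise ValueError("mu, k and T must be positive")


def _fixation_rate_factor(G):
    """G / (1 - exp(-G)), the substitution-rate inflation relative to
    neutral; -> 1 as G -> 0, -> G for large G.  Stable via expm1."""
    G = np.asarray(G, dtype=float)
    out = np.ones_like(G)
    pos = G > 1e-12
    out[pos] = G[pos] / (-np.expm1(-G[pos]))
    return out


def loss_probability(G, params: LifespanParams = LifespanParams()):
    """Probability that a motif acquires >= 1 disrupting substitution in T
    generations under constant conversion intensity G (vectorized)."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("G must be non-negative")
    lam = params.mu * params.k * params.T * _fixation_rate_factor(G)
    return -np.expm1(-lam)


def expected_loss_fraction(
    dist: GDistribution,
    params: LifespanParams = LifespanParams(),
    quantile_range: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Mean loss probability E[P(G)] with G drawn from ``dist``,
    conditioned on the given quantile range of the full (zero-inflated)
    distribution.

    Computed by adaptive quadrature on the quantile scale (relative
    accuracy 1e-6); the zero-rate point mass maps to G = 0.
    """
    q_lo, q_hi = quantile_range
    if not (0.0 <= q_lo < q_hi <= 1.0):
        raise ValueError("quantile range must satisfy 0 <= q_lo < q_hi <= 1")
    p0 = dist.zero_fraction

    def integrand(u: float) -> float:
        if u <= p0:
            g = 0.0
        else:
            g = stats.gamma.ppf(
                (u - p0) / (1.0 - p0), dist.shape, scale=dist.gamma_scale
            )
        return float(loss_probability(np.array(g), params))

    pieces = sorted({q_lo, q_hi} | ({p0} if q_lo < p0 < q_hi else set()))
    total = 0.0
    for lo, hi in zip(pieces[:-1], pieces[1:]):
        val, _ = integrate.quad(integrand, lo, hi, epsrel=1e-6, limit=200)
        total += val
    return total / (q_hi - q_lo)


def calibrate_tail_mean(
    shape: float,
    tail_q: float,
    target_tail_mean: float,
    m_x: float | None = None,
) -> tuple[float, float | None]:
    """Solve for the gamma mean M_G such that E[G | G > quantile(tail_q)]
    equals ``target_tail_mean``; returns (M_G, c) with c = M_G / m_x when a
    crossover-rate mean is supplied.

    The conditional tail mean is strictly increasing in M_G (gamma is a
    scale family), so a bracketed root search converges; tolerance 1e-8
    relative.
    """
    if shape <= 0:
        raise ValueError("shape must be positive")
    if not 0.0 < tail_q < 1.0:
        raise ValueError("tail_q must lie in (0, 1)")
    if target_tail_mean <= 0:
        raise ValueError("target tail mean must be positive")

    def tail_mean(mean: float) -> float:
        sc = mean / shape
        gq = stats.gamma.ppf(tail_q, shape, scale=sc)
        return float(
            mean * stats.gamma.sf(gq, shape + 1.0, scale=sc) / (1.0 - tail_q)
        )

    lo, hi = target_tail_mean * 1e-6, target_tail_mean * 1e3
    f = lambda m: tail_mean(m) - target_tail_mean
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(
            f"no root in bracket [{lo:.3g}, {hi:.3g}]: "
            f"f(lo)={f(lo):.3g}, f(hi)={f(hi):.3g}"
        )
    mean = float(optimize.brentq(f, lo, hi, rtol=1e-10))
    return mean, (mean / m_x if m_x is not None else None)


# ---------------------------------------------------------------------------
# Diffusion helpers (fixation probability and conditional fixation time)
# ---------------------------------------------------------------------------


def kimura_fixation_probability(G: float, N: int, x0: float | None = None) -> float:
    """Diffusion fixation probability (1 - exp(-G*x0)) / (1 - exp(-G)) of an
    allele at initial frequency x0 (default a new mutant, 1/(2N))."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if G < 0:
        raise ValueError("G must be non-negative")
    if x0 is None:
        x0 = 1.0 / (2 * N)
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    if G < 1e-12:
        return x0
    return float(-np.expm1(-G * x0) / -np.expm1(-G))


def kimura_mean_fixation_time(G: float, N: int) -> float:
    """Mean number of generations to fixation of a new semidominant mutant,
    conditional on fixation, under scaled conversion/selection G = 4*N*g.

    From the diffusion Green's function with drift G*x*(1-x)/(4N) and
    variance x*(1-x)/(2N):

        t* = 4N / (G*(1-e^{-G})) * Int_0^1 (1-e^{-Gx})(1-e^{-G(1-x)})
                                            / (x*(1-x)) dx

    with the neutral limit 4N.  The integrand is bounded (it tends to
    G*(1-e^{-G}) at both endpoints); the integral is evaluated by adaptive
    quadrature split at the exp(-G*x) boundary layers.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if G < 0:
        raise ValueError("G must be non-negative")
    if G < 1e-8:
        return 4.0 * N

    def f(x: float) -> float:
        return float(
            -np.expm1(-G * x) * -np.expm1(-G * (1.0 - x)) / (x * (1.0 - x))
        )

    cuts = sorted({0.0, 1.0} | {c / G for c in (1.0, 10.0) if c / G < 0.5}
                  | {1.0 - c / G for c in (1.0, 10.0) if c / G < 0.5} | {0.5})
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        val, err = integrate.quad(f, lo, hi, epsrel=1e-10, limit=400)
        if not np.isfinite(val):
            raise RuntimeError(f"quadrature failure on [{lo}, {hi}]: err={err}")
        total += val
    return float(4.0 * N * total / (G * -np.expm1(-G)))
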