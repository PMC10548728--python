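"""Recurrent selective-sweep hitchhiking model linking the scale factor
lambda to the selection intensity s.

A target of ``m_s`` bases in the middle of a neutral region undergoes
recurrent sweeps: beneficial mutations (heterozygote fitness 1 + s) arise at
per-site rate mu, fix with probability p_f, and each fixation drags linked
neutral variation along unless recombination lets it escape.  For a neutral
site at recombination distance c (Morgans) the single-sweep escape
probability is

    h(c) = (2c/s) * alpha^(-2c/s) * Gamma(-2c/s, 1/alpha),  alpha = 2 N s,

with Gamma the upper incomplete gamma function (negative shape).  Sweeps
that catch the site arrive at rate k_h(c) = 2 N m_f (1 - h(c)) per 2N
generations, shortening the pairwise coalescent time by 1/(1 + k_h) and
hence the expected heterozygosity to H = 4 N mu / (1 + k_h).  Averaging
H/H_neutral over the L' flanking sites gives lambda as a decreasing function
of s, which is inverted numerically to estimate the selection intensity from
a fitted lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import mpmath
import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaincc, gammaln

# beyond this negative shape the float64 downward recurrence loses accuracy;
# switch to arbitrary precision
_RECURRENCE_MAX_STEPS = 60


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of the recurrent-sweep model.

    N: diploid effective size; mu: per-site per-generation mutation rate;
    rho: per-site recombination rate (Morgans/bp/generation); m_s: length of
    the selected target (bp); L_prime: flanking neutral length per side (bp;
    by symmetry the average over one flank equals the average over both);
    s: heterozygote selection advantage.
    """

    N: float
    mu: float = 2.5e-8
    rho: float = 1e-8
    m_s: int = 50
    L_prime: int = 5000
    s: float | None = None

    def __post_init__(self) -> None:
        if min(self.N, self.mu, self.rho) <= 0 or self.m_s < 1 or self.L_prime < 1:
            raise ValueError("sweep parameters must be positive")
        if self.s is not None and not (0 < self.s <= 1):
            raise ValueError("selection intensity must be in (0, 1]")


def _scaled_upper_gamma(a: np.ndarray, alpha: float) -> np.ndarray:
    """alpha^a * Gamma(a, 1/alpha) for shapes a <= 0, vectorised.

    Uses the scaled downward recurrence
        G(a) = (G(a+1)/alpha - exp(-1/alpha)) / a,   G(a) := alpha^a Gamma(a, 1/alpha)
    seeded from a positive shape in (0, 1] where Gamma(a, x) =
    gammaincc(a, x) * Gamma(a) is available, with an arbitrary-precision
    fallback for very negative shapes.
    """
    a = np.asarray(a, dtype=float)
    x = 1.0 / alpha
    out = np.empty_like(a)
    steps = np.floor(-a).astype(int) + 1  # a + steps in (0, 1]
    # near-integer shapes make the recurrence pass through a ~0/0 step;
    # delegate those (and very deep recurrences) to arbitrary precision
    near_int = np.abs(a - np.round(a)) < 1e-6
    deep = (steps > _RECURRENCE_MAX_STEPS) | near_int
    for idx in np.nonzero(deep)[0]:
        out[idx] = float(mpmath.power(alpha, a[idx])
                         * mpmath.gammainc(a[idx], x, mpmath.inf))
    shallow = ~deep
    if np.any(shallow):
        a_s = a[shallow]
        m = steps[shallow]
        a0 = a_s + m
        g = alpha ** a0 * gammaincc(a0, x) * np.exp(gammaln(a0))
        ex = math.exp(-x)
        remaining = m.copy()
        cur = a0
        active = remaining > 0
        while np.any(active):
            cur = np.where(active, cur - 1.0, cur)
            g = np.where(active, (g / alpha - ex) / cur, g)
            remaining = remaining - active
            active = remaining > 0
        out[shallow] = g
    return out


def escape_prob(c, s: float, N: float):
    """Single-sweep escape probability h(c) of a neutral locus at
    recombination distance c (Morgans) from a sweeping site.

    Scalar or array c; h(0) = 0, h increases with c, and h(inf) = 1 (a fully
    unlinked locus; at any finite c the model value is bounded by
    exp(-1/(2Ns)))."""
    if s <= 0:
        raise ValueError("selection intensity must be positive")
    if N <= 0:
        raise ValueError("population size must be positive")
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(c_arr < 0):
        raise ValueError("recombination distance must be nonnegative")
    alpha = 2.0 * N * s
    a = -2.0 * c_arr / s
    out = np.zeros_like(c_arr)
    inf_mask = np.isinf(c_arr)
    out[inf_mask] = 1.0
    pos = (~inf_mask) & (c_arr > 0)
    if np.any(pos):
        out[pos] = -a[pos] * _scaled_upper_gamma(a[pos], alpha)
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(c) or np.ndim(c) == 0:
        return float(out[0])
    return out


def escape_prob_quadrature(c: float, s: float, N: float,
                           rtol: float = 1e-10) -> float:
    """Arbitrary-precision quadrature evaluation of h(c) (slow reference)."""
    if c == 0:
        return 0.0
    alpha = mpmath.mpf(2) * N * s
    a = mpmath.mpf(-2) * c / s
    val = (-a) * mpmath.power(alpha, a) * mpmath.gammainc(a, 1 / alpha, mpmath.inf)
    return float(val)


def fixation_prob(s: float, N: float) -> float:
    """Fixation probability of a new beneficial mutation,
    (1 - e^{-2s}) / (1 - e^{-4Ns}); continuous limit 1/(2N) at s = 0."""
    if N < 1:
        raise ValueError("population size must be >= 1")
    if s == 0.0:
        return 1.0 / (2.0 * N)
    num = -math.expm1(-2.0 * s)
    den = -math.expm1(-4.0 * N * s)
    return num / den


def substitution_rate(cfg: SweepConfig) -> float:
    """Expected beneficial substitutions per generation in the target,
    m_f = 2 N mu m_s p_f."""
    if cfg.s is None:
        raise ValueError("SweepConfig.s is not set")
    return 2.0 * cfg.N * cfg.mu * cfg.m_s * fixation_prob(cfg.s, cfg.N)


def hitchhike_rate(c, cfg: SweepConfig):
    """Rate k_h(c) (per 2N generations) of sweeps that carry the neutral
    locus to fixation: 2 N m_f (1 - h(c))."""
    m_f = substitution_rate(cfg)
    h = escape_prob(c, cfg.s, cfg.N)
    return 2.0 * cfg.N * m_f * (1.0 - h)


def lambda_from_s(cfg: SweepConfig) -> float:
    """Expected diversity-reduction factor lambda under recurrent sweeps:
    the discrete per-site average (1/L') sum_{l=1}^{L'} 1/(1 + k_h(l rho))."""
    c = cfg.rho * np.arange(1, cfg.L_prime + 1, dtype=float)
    k_h = hitchhike_rate(c, cfg)
    return float(np.mean(1.0 / (1.0 + k_h)))


def infer_s(lambda_hat: float, cfg: SweepConfig,
            bounds: tuple[float, float] = (1e-5, 0.5),
            rtol: float = 1e-6) -> float | None:
    """Invert lambda(s) = lambda_hat for the selection intensity.

    Returns None when lambda_hat >= 1 (no directional-sweep solution) or when
    lambda_hat lies below the reachable range on the search interval.  The
    monotone decrease of lambda(s) over the interval is asserted before
    inversion.
    """
    if lambda_hat <= 0:
        raise ValueError("lambda must be positive")
    if lambda_hat >= 1.0:
        return None
    lo, hi = bounds
    grid = np.geomspace(lo, hi, 25)
    lam_grid = np.array([lambda_from_s(replace(cfg, s=float(v))) for v in grid])
    if np.any(np.diff(lam_grid) > 1e-12):
        raise RuntimeError("lambda(s) is not monotone decreasing on the search interval")
    if lambda_hat > lam_grid[0] or lambda_hat < lam_grid[-1]:
        return None

    def f(ln_s: float) -> float:
        return lambda_from_s(replace(cfg, s=math.exp(ln_s))) - lambda_hat

    root = brentq(f, math.log(lo), math.log(hi), xtol=rtol / 10.0, rtol=1e-15)
    return float(math.exp(root))
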