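"""Low-level numerical kernels for the two-species site-spectrum model.

Everything here works on the coalescent time scale tau = t / (2N) for a
diploid population of size N, where the number of ancestral lineages of a
sample follows a pure-death Markov chain with death rate beta_k = k(k-1)/2
while k lineages remain.  The kernels are deliberately free of any model
state: they depend only on sample sizes and scaled times, so they can be
cached aggressively by the fitting code.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.special import comb, gammaln

# Spectral coefficients (Tavare-style alternating sums) grow combinatorially
# with n; beyond this sample size the float64 evaluation loses too much
# precision and we fall back to the matrix exponential.
SPECTRAL_MAX_N = 25


def death_rates(n: int) -> np.ndarray:
    """Coalescence rates beta_k = k(k-1)/2 for k = 1..n (scaled time)."""
    k = np.arange(1, n + 1, dtype=float)
    return k * (k - 1.0) / 2.0


def _generator(n: int) -> np.ndarray:
    """Column-convention generator Q of the block-counting chain, states 1..n."""
    beta = death_rates(n)
    q = np.zeros((n, n))
    for j in range(n):  # state j+1
        q[j, j] = -beta[j]
        if j + 1 < n:
            q[j, j + 1] = beta[j + 1]
    return q


@lru_cache(maxsize=256)
def _spectral_coeffs(n: int) -> tuple[np.ndarray, float]:
    """Exact spectral decomposition of the pure-death chain started from n.

    Returns (c, maxcoef) with g_m(tau) = sum_k c[m-1, k-1] * exp(-beta_k tau).
    The eigenvectors are computed in exact rational arithmetic so the only
    error in evaluation is the final float64 cancellation, bounded by
    maxcoef * machine-eps.
    """
    beta = [Fraction(k * (k - 1), 2) for k in range(0, n + 1)]  # beta[k], k=0..n
    # right eigenvectors: v^{(k)}_j for j <= k, v_k = 1
    vecs: list[dict[int, Fraction]] = [{}]  # index 0 unused
    for k in range(1, n + 1):
        v = {k: Fraction(1)}
        for j in range(k - 1, 0, -1):
            v[j] = beta[j + 1] * v[j + 1] / (beta[j] - beta[k])
        vecs.append(v)
    # expand e_n in the eigenbasis: a_n = 1, downward substitution
    a = [Fraction(0)] * (n + 1)
    a[n] = Fraction(1)
    for j in range(n - 1, 0, -1):
        a[j] = -sum(a[k] * vecs[k].get(j, Fraction(0)) for k in range(j + 1, n + 1))
    c = np.zeros((n, n))
    for m in range(1, n + 1):
        for k in range(m, n + 1):
            c[m - 1, k - 1] = float(a[k] * vecs[k].get(m, Fraction(0)))
    return c, float(np.abs(c).max())


def lineage_kernel_expm(n: int, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """(g, W) for a sample of n at scaled time tau via one augmented expm.

    g[m-1] = P(m ancestral lineages at tau | n at 0);
    W[m-1] = E[time spent with m lineages on [0, tau]] (scaled units,
    unconditional on the state at tau).
    """
    if n == 1:
        return np.ones(1), np.array([tau])
    q = _generator(n)
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = q
    aug[:n, n:] = np.eye(n)
    e = expm(aug * tau)
    g = e[:n, n - 1].copy()
    w = e[:n, 2 * n - 1].copy()
    np.clip(g, 0.0, 1.0, out=g)
    np.clip(w, 0.0, tau if tau > 0 else 0.0, out=w)
    return g, w


def lineage_kernel(n: int, tau) -> tuple[np.ndarray, np.ndarray]:
    """(g, W) as in :func:`lineage_kernel_expm`; tau may be a scalar or 1-D array.

    Uses the spectral form for n <= SPECTRAL_MAX_N (vectorised over tau),
    otherwise falls back to the matrix exponential per tau value.
    """
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau_arr < 0) or not np.all(np.isfinite(tau_arr)):
        raise ValueError("scaled times must be finite and nonnegative")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    scalar = np.isscalar(tau) or np.ndim(tau) == 0
    if n == 1:
        g = np.ones((1, tau_arr.size))
        w = tau_arr[None, :].copy()
    elif n <= SPECTRAL_MAX_N:
        c, _ = _spectral_coeffs(n)
        beta = death_rates(n)
        ex = np.exp(-np.outer(beta, tau_arr))          # (n, T)
        g = c @ ex
        basis = np.empty_like(ex)
        basis[0] = tau_arr
        basis[1:] = (1.0 - ex[1:]) / beta[1:, None]
        w = c @ basis
        np.clip(g, 0.0, 1.0, out=g)
        np.clip(w, 0.0, None, out=w)
    else:
        g = np.empty((n, tau_arr.size))
        w = np.empty((n, tau_arr.size))
        for t_idx, t in enumerate(tau_arr):
            g[:, t_idx], w[:, t_idx] = lineage_kernel_expm(n, t)
    if scalar:
        return g[:, 0], w[:, 0]
    return g, w


def sojourn_numerator(n: int, k: int, tau: float) -> np.ndarray:
    """Van Loan block integral: vector over end-states m of
    [ int_0^tau e^{Q(tau-t)} E_kk e^{Qt} dt ]_{m, n}  (scaled time units)."""
    if n == 1:
        return np.array([tau if k == 1 else 0.0])
    q = _generator(n)
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = q
    aug[n:, n:] = q
    aug[k - 1, n + k - 1] = 1.0
    e = expm(aug * tau)
    return np.clip(e[:n, 2 * n - 1].copy(), 0.0, None)


# ---------------------------------------------------------------------------
# combinatorial kernels (sample-size only; cached per (n1, n2))
# ---------------------------------------------------------------------------

def polya_matrix(n: int) -> np.ndarray:
    """P[m, k, i]: probability that k of the m ancestral lineages of a sample
    of n subtend exactly i of the n sampled lineages (Polya-Eggenberger).

    Shape (n+1, n+1, n+1); entries with k > m or m > n are zero.  k = 0 is the
    point mass at i = 0 and k = m < n the point mass at i = n (all ancestors
    in the focal class carry the allele).
    """
    p = np.zeros((n + 1, n + 1, n + 1))
    for m in range(1, n + 1):
        p[m, 0, 0] = 1.0
        for k in range(1, m + 1):
            if k == m:
                # all m ancestors belong to the focal class
                p[m, k, n if m < n else k] = 1.0
                if m == n:
                    p[m, k, k] = 1.0  # identity case: i = k (= n here only if k=n)
                continue
            denom = comb(n - 1, m - 1)
            for i in range(k, n - (m - k) + 1):
                p[m, k, i] = comb(i - 1, k - 1) * comb(n - i - 1, m - k - 1) / denom
    return p


def hypergeom_split(k1: int, k2: int, m1: int, m2: int) -> float:
    """P that a mutation carried by k1+k2 of m1+m2 exchangeable ancestral
    lineages is split (k1, k2) between the two descendant ancestor sets."""
    return float(comb(m1, k1) * comb(m2, k2) / comb(m1 + m2, k1 + k2))


@lru_cache(maxsize=32)
def ancient_tensor(n1: int, n2: int) -> np.ndarray:
    """C[m1-1, m2-1, i, j]: combinatorial kernel of the ancestral ("ancient")
    component of the joint spectrum.  The per-site expectation is
    theta0 * sum_{m1,m2} g1[m1] g2[m2] C[m1,m2,i,j] with theta0 = 4 N0 mu.

    Derived allele counts k1+k2 run over 1..m1+m2-1: sites carried by all
    ancestral lineages are monomorphic-derived in both samples and belong to
    the ignored "fixed same allele" class.
    """
    p1 = polya_matrix(n1)
    p2 = polya_matrix(n2)
    c = np.zeros((n1, n2, n1 + 1, n2 + 1))
    for m1 in range(1, n1 + 1):
        for m2 in range(1, n2 + 1):
            wt = np.zeros((m1 + 1, m2 + 1))
            for k1 in range(m1 + 1):
                for k2 in range(m2 + 1):
                    k = k1 + k2
                    if 1 <= k <= m1 + m2 - 1:
                        wt[k1, k2] = hypergeom_split(k1, k2, m1, m2) / k
            c[m1 - 1, m2 - 1] = np.einsum(
                "ki,lj,kl->ij", p1[m1, : m1 + 1], p2[m2, : m2 + 1], wt
            )
    return c


@lru_cache(maxsize=64)
def new_site_matrix(n: int) -> np.ndarray:
    """M[i-1, k-1] with i = 1..n-1, k = 1..n such that the per-site expected
    "new" spectrum is mu * (M @ W_gen), W_gen the expected per-state sojourn
    times (generations) of the within-species coalescent truncated at the
    split.  M[i, k] = (n-i-1)!(i-1)!/(n-1)! * k(k-1) * C(n-k, i-1)."""
    if n < 2:
        return np.zeros((0, n))
    m = np.zeros((n - 1, n))
    for i in range(1, n):
        lcomb = gammaln(n - i) + gammaln(i) - gammaln(n)
        for k in range(2, n + 1):
            m[i - 1, k - 1] = k * (k - 1) * comb(n - k, i - 1) * np.exp(lcomb)
    return m


@lru_cache(maxsize=32)
def summary_kernels(n1: int, n2: int) -> dict:
    """Category-contracted ancient kernels: for each of the four observable
    summaries, the matrix A[m1-1, m2-1] such that the per-site ancient
    contribution is theta0 * g1 @ A @ g2."""
    c = ancient_tensor(n1, n2)
    mask_s1 = np.zeros((n1 + 1, n2 + 1))
    mask_s1[1:n1, 0] = 1.0
    mask_s1[1:n1, n2] = 1.0
    mask_s2 = np.zeros((n1 + 1, n2 + 1))
    mask_s2[0, 1:n2] = 1.0
    mask_s2[n1, 1:n2] = 1.0
    mask_s12 = np.zeros((n1 + 1, n2 + 1))
    mask_s12[1:n1, 1:n2] = 1.0
    mask_d = np.zeros((n1 + 1, n2 + 1))
    mask_d[n1, 0] = 1.0
    mask_d[0, n2] = 1.0
    return {
        "S1": np.einsum("mnij,ij->mn", c, mask_s1),
        "S2": np.einsum("mnij,ij->mn", c, mask_s2),
        "S12": np.einsum("mnij,ij->mn", c, mask_s12),
        "D": np.einsum("mnij,ij->mn", c, mask_d),
    }
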