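"""Expected joint site-frequency spectrum and summary statistics for two
species that split from a common ancestor of constant size.

The model: an ancestral diploid population of size ``N0`` splits ``Td``
generations ago into two descendant species of diploid sizes ``N1`` and
``N2``.  A sample of ``n1`` and ``n2`` haploid sequences is taken from the
two species at present.  Under the infinite-sites assumption the expected
number of sites with ``i`` derived copies in sample 1 and ``j`` in sample 2
(the joint allele frequency spectrum, JAFS) decomposes into "ancient"
variation that arose before the split and "new" mutations that arose on the
two descendant branches; the four observable window summaries

* ``S1`` – sites segregating within species 1 only,
* ``S2`` – sites segregating within species 2 only,
* ``S12`` – sites segregating in both species,
* ``D``  – sites fixed for different alleles in the two samples,

are sums of JAFS entries, with ``S12`` receiving an extra double-mutation
(recurrent) term since independent new mutations at the same site in both
species also produce shared polymorphism.

Locus-specific selection is modelled by scaling the descendant sizes with
positive factors ``lambda1`` and ``lambda2`` (recurrent positive selection
mimics ``lambda < 1``: less polymorphism, more divergence; balancing
selection mimics ``lambda > 1``).  The ancestral size is never scaled.

All four summaries are invariant to which allele is called derived, so the
observed counts need no ancestral-state polarisation (no outgroup): the
categories pair each polarised JAFS entry with its fold-complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from . import kernels


@dataclass(frozen=True)
class DemographicModel:
    """Global split-model parameters (diploid sizes, generations)."""

    N0: float
    N1: float
    N2: float
    Td: float
    mu_ref: float = 2.5e-8

    def __post_init__(self) -> None:
        if min(self.N0, self.N1, self.N2) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.Td < 0:
            raise ValueError("divergence time must be nonnegative")
        if self.mu_ref <= 0:
            raise ValueError("reference mutation rate must be positive")


@dataclass(frozen=True)
class LocusParams:
    """Locus-specific parameters: size scaling factors, mutation rate, length."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    mu_l: float = 2.5e-8
    length: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda factors must be positive")
        if self.mu_l <= 0:
            raise ValueError("locus mutation rate must be positive")
        if self.length < 1:
            raise ValueError("locus length must be >= 1 bp")


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes from the two species."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")


@dataclass(frozen=True)
class ExpectedQuad:
    """Expected counts of the four summaries for one locus."""

    ES1: float
    ES2: float
    ES12: float
    ED: float
    ES12_recurrent: float = 0.0


def lineage_dist(n: int, T: float, N: float) -> np.ndarray:
    """Distribution of the number of ancestral lineages of a sample of ``n``
    haplotypes ``T`` generations ago in a diploid population of size ``N``.

    Returns the probability vector over m = 1..n (index m-1).  Computed from
    the matrix exponential / exact spectral form of the pure-death chain with
    rate C(k,2)/(2N) per generation, which is stable where the classical
    alternating-series expression is not.
    """
    if not np.isfinite(T) or T < 0 or not np.isfinite(N) or N <= 0:
        raise ValueError("T must be finite >= 0 and N finite > 0")
    g, _ = kernels.lineage_kernel(int(n), T / (2.0 * N))
    return g


def polya_subtend(n: int, m: int, k: int) -> np.ndarray:
    """Probability vector (over i = 0..n) that ``k`` of the ``m`` ancestral
    lineages of a sample of ``n`` subtend exactly ``i`` sampled lineages."""
    if not (1 <= k <= m <= n):
        raise ValueError("need 1 <= k <= m <= n")
    return kernels.polya_matrix(n)[m, k].copy()


def ancestral_split_prob(k1: int, k2: int, m1: int, m2: int) -> float:
    """Probability that a mutation carried by k1+k2 of the m1+m2 ancestral
    lineages splits as (k1, k2) between the two descendant ancestor sets."""
    if not (0 <= k1 <= m1 and 0 <= k2 <= m2) or k1 + k2 < 1:
        raise ValueError("inadmissible carrier counts")
    return kernels.hypergeom_split(k1, k2, m1, m2)


def ancestral_afs(k: int, N0: float, mu: float) -> float:
    """Expected per-site density of ancestral sites with derived-allele count
    ``k`` among the ancestral lineages: theta0 / k with theta0 = 4*N0*mu
    (the equilibrium diploid frequency spectrum)."""
    if k < 1:
        raise ValueError("derived-allele count must be >= 1")
    return 4.0 * N0 * mu / k


def cond_sojourn_time(n: int, m: int, k: int, T: float, N: float) -> float:
    """E[time spent with exactly ``k`` lineages on [0, T] | the sample of
    ``n`` has ``m`` ancestors at T], in generations.

    Evaluated as the Markov-bridge occupancy integral
    int_0^T g_{n,k}(t) g_{k,m}(T-t) dt / g_{n,m}(T), computed exactly with a
    Van Loan augmented matrix exponential.
    """
    if not (1 <= m <= k <= n):
        raise ValueError("need m <= k <= n")
    if T < 0:
        raise ValueError("T must be nonnegative")
    tau = T / (2.0 * N)
    g, _ = kernels.lineage_kernel(n, tau)
    denom = g[m - 1]
    if denom <= 0.0:
        raise ValueError("conditioning on an impossible lineage count")
    num = kernels.sojourn_numerator(n, k, tau)[m - 1]
    return 2.0 * N * num / denom


def _cond_sojourn_quad(n: int, m: int, k: int, T: float, N: float) -> float:
    """Adaptive-quadrature evaluation of the same bridge integral (slow;
    used as an internal cross-check)."""
    tau = T / (2.0 * N)
    g, _ = kernels.lineage_kernel(n, tau)

    def integrand(t: float) -> float:
        g1, _ = kernels.lineage_kernel(n, t)
        g2, _ = kernels.lineage_kernel(k, tau - t)
        return g1[k - 1] * g2[m - 1]

    val, _ = quad(integrand, 0.0, tau, epsrel=1e-8, limit=200)
    return 2.0 * N * val / g[m - 1]


def _species_new_vector(n: int, n_eff: float, mu: float, length: float,
                        Td: float) -> np.ndarray:
    """Expected new-mutation spectrum of one species: vector over i = 1..n.

    Entries i < n are segregating classes; the i = n entry is the expected
    number of sites fixed for a new allele in the sample (mutations on the
    stem branch between the sample MRCA and the split), which feed the
    divergence class of the joint spectrum.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    tau = Td / (2.0 * n_eff)
    _, w = kernels.lineage_kernel(n, tau)
    w_gen = 2.0 * n_eff * w  # per-state sojourn, generations
    out = np.zeros(n)
    if n >= 2:
        out[: n - 1] = mu * length * (kernels.new_site_matrix(n) @ w_gen)
    out[n - 1] = mu * length * w_gen[0]
    return out


def jafs_new(n: int, N_eff: float, locus: LocusParams, Td: float) -> np.ndarray:
    """Expected spectrum of mutations younger than the split in one species
    (vector over derived count i = 1..n; see :func:`_species_new_vector`)."""
    return _species_new_vector(n, N_eff, locus.mu_l, locus.length, Td)


def jafs_ancient(cfg: SampleConfig, model: DemographicModel,
                 locus: LocusParams) -> np.ndarray:
    """Expected JAFS contribution of variation older than the split.

    (n1+1) x (n2+1) matrix; descendant lineage survival uses the scaled sizes
    lambda1*N1 and lambda2*N2, the ancestral spectrum uses N0 unscaled.
    """
    n1, n2 = cfg.n1, cfg.n2
    g1, _ = kernels.lineage_kernel(n1, model.Td / (2.0 * locus.lambda1 * model.N1))
    g2, _ = kernels.lineage_kernel(n2, model.Td / (2.0 * locus.lambda2 * model.N2))
    c = kernels.ancient_tensor(n1, n2)
    theta0 = 4.0 * model.N0 * locus.mu_l
    return theta0 * locus.length * np.einsum("m,n,mnij->ij", g1, g2, c)


def expected_jafs(cfg: SampleConfig, model: DemographicModel,
                  locus: LocusParams) -> np.ndarray:
    """Total expected JAFS: ancient component plus new mutations placed on
    the margins (i, 0) and (0, j).  Entries (0,0) and (n1,n2) are zero by
    convention (unobservable / monomorphic classes)."""
    n1, n2 = cfg.n1, cfg.n2
    out = jafs_ancient(cfg, model, locus)
    nu1 = jafs_new(n1, locus.lambda1 * model.N1, locus, model.Td)
    nu2 = jafs_new(n2, locus.lambda2 * model.N2, locus, model.Td)
    out[1:, 0] += nu1
    out[0, 1:] += nu2
    out[0, 0] = 0.0
    out[n1, n2] = 0.0
    return out


def recurrent_shared(cfg: SampleConfig, model: DemographicModel,
                     locus: LocusParams) -> float:
    """Expected shared polymorphisms from independent recurrent mutation.

    Per-site double-mutation model: L * p1 * p2 with p_k the per-site
    probability that a site carries a new-mutation polymorphism in species k
    (infinite sites within a lineage, independent across lineages).
    Vanishes at Td = 0 and scales with mu^2.
    """
    nu1 = jafs_new(cfg.n1, locus.lambda1 * model.N1, locus, model.Td)
    nu2 = jafs_new(cfg.n2, locus.lambda2 * model.N2, locus, model.Td)
    p1 = float(nu1[: cfg.n1 - 1].sum()) / locus.length
    p2 = float(nu2[: cfg.n2 - 1].sum()) / locus.length
    return locus.length * p1 * p2


def expected_summaries(cfg: SampleConfig, model: DemographicModel,
                       locus: LocusParams) -> ExpectedQuad:
    """Expected values of the four observable window summaries."""
    n1, n2 = cfg.n1, cfg.n2
    e = expected_jafs(cfg, model, locus)
    es1 = float(e[1:n1, 0].sum() + e[1:n1, n2].sum())
    es2 = float(e[0, 1:n2].sum() + e[n1, 1:n2].sum())
    es12p = recurrent_shared(cfg, model, locus)
    es12 = es12p + float(e[1:n1, 1:n2].sum())
    ed = float(e[0, n2] + e[n1, 0])
    return ExpectedQuad(ES1=es1, ES2=es2, ES12=es12, ED=ed, ES12_recurrent=es12p)
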