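# Methods

## Model

`hkascan` treats the four per-window summaries (S1, S2, S12, D) as
independent Poisson counts whose means are exact expectations under a
neutral two-species split model with locus-specific size-scaling factors.
Assumptions: random mating in all three populations, constant diploid sizes
(N0 ancestral; λ1·N1 and λ2·N2 in the descendants), a clean split with no
gene flow, infinite sites within a lineage, and a known reference per-site
mutation rate. Time is measured in generations with pairwise coalescent
rate 1/(2N); all population sizes are diploid, so the equilibrium
heterozygosity scale is θ = 4Nμ.

The expected joint allele frequency spectrum (JAFS) of samples of n1 and n2
haplotypes is the sum of two components.

**Ancient component.** Each sample's lineage count at the split follows the
pure-death chain g_{n,m}(T_d) with rate C(k,2)/(2λN) per generation. Given
m1 and m2 surviving ancestral lineages, an ancestral variant at frequency
class k among the m1+m2 exchangeable lineages splits hypergeometrically
between the two ancestor sets, and k of m ancestors subtend i of n sampled
lineages with the Polya–Eggenberger probability
C(i−1,k−1)C(n−i−1,m−k−1)/C(n−1,m−1). The ancestral standing-variation
spectrum is θ0/k with θ0 = 4N0μ for k = 1..m1+m2−1; the class carried by
*all* ancestral lineages is monomorphic-derived in both samples and is
excluded (it belongs to the unobservable "fixed, same allele" category).

**New component.** Mutations younger than the split contribute to the JAFS
margins. For derived counts i < n the expectation combines the per-state
expected sojourn times of the within-species coalescent truncated at T_d
with the standard combinatorial size-of-a-subtended-class factor; summed
over the lineage-count distribution at T_d this collapses to the
*unconditional* occupancy W_k = ∫₀^{T_d} g_{n,k}(t) dt, which the
implementation exploits. The i = n class — mutations on the stem branch
between the sample MRCA and the split — is exactly μ·W_1 per site and feeds
the divergence category; it is what makes the n1 = n2 = 1 limit come out as
the textbook pairwise divergence 2μ(T_d + 2N0).

**Recurrent shared polymorphism.** Independent new mutations at the same
site in both species also produce shared polymorphism. We model this as a
per-site double-hit probability, ES12′ = L·p1·p2 with p_k the per-site
probability of a new-mutation polymorphism in species k. This term vanishes
at T_d = 0, scales with μ², and dominates observable sharing once T_d
exceeds a few 2N (when ancestral sharing has decayed as e^{−T_d/2N}). The
structured-coalescent test oracle is infinite-sites and therefore carries
no such term; oracle comparisons use ES12 − ES12′.

## Inference

Two-step maximum likelihood. Step one maximises the product-Poisson
likelihood over (N0, N1, N2, T_d) with λ ≡ 1 and μ fixed at the reference
rate; because every window shares the same per-site expectations, the
likelihood depends on the data only through total counts and total
effective length, making the fit exactly invariant to window order. The
optimiser is Nelder–Mead on log parameters with three deterministic starts
(init, ×0.5, ×1.5) and function tolerance 1e−8; bounds N ∈ [10, 1e8],
T_d ∈ [1, 1e9]; non-convergence is reported in the returned diagnostics and
warned about, never silently dropped.

Step two fits (λ1, λ2, μ_l) per window with the demography fixed. The
locus mutation rate enters all four means linearly (plus the μ² recurrent
term), so μ_l is profiled out in closed form refined by a short Newton
iteration; the λ surface is explored by a deterministic hierarchical grid —
a shared coarse log grid over λ ∈ [1e−4, 1e4] followed by three ten-fold
zooms (final resolution ≈ 0.2% in log λ) — optionally polished by a
Nelder–Mead simplex. The bounds extend to 1e−4 because genuinely swept
windows can fit λ below 1e−3; estimates on a bound are flagged, as are
all-zero-count windows (μ_l at its 1e−12 floor). Expectations are clamped
at 1e−12 before taking logs so that zero-expectation categories (e.g. D at
T_d = 0) keep the likelihood finite.

The per-λ model evaluation is made cheap by a kernel decomposition: the
combinatorial tensors (Polya, hypergeometric-split, new-site matrix) depend
only on (n1, n2) and are cached; per λ the only work is evaluating
(g, W) of the pure-death chain at τ = T_d/(2λN). Those are computed
spectrally with eigenvectors obtained once per n in exact rational
arithmetic (the classical alternating-series form of g_{n,m} is
catastrophically unstable, but with exact coefficients the only error is
the final float64 cancellation, ≤ coefficient-magnitude × machine-eps —
verified ≤ 5e−10 against the matrix exponential up to n = 25, above which
the implementation switches to the matrix exponential of the augmented
(Van Loan) generator, which also yields the integrated occupancies W in the
same call). Grid and polish paths evaluate the identical kernels, and a
test pins the fast path to the direct model evaluation at 1e−9.

## Significance

*Box-Cox procedure.* The genome-wide distributions of λ̂1 and λ̂2 are
normalised separately with a one-parameter Box-Cox transform (exponent by
profile ML of normality, then standardisation). Calls use the fixed normal
quantile 3.2905 (one-tailed p = 5e−4): z < −3.2905 positive selection,
z > +3.2905 balancing. Boundary-flagged windows are excluded from the
normalisation fit but still scored. The transform is monotone, so calls are
a pure quantile rule on λ̂. The normalisation is fitted once on all
windows; we do not iterate after removing significant windows — at genome
scale the significant fraction (~1e−3) cannot move the fit materially.
The calibration test in the suite measures the neutral two-tailed call
rate at this threshold on 1e5 model-generated windows: it comes out near
but slightly above nominal (≈1.1e−3 for species 1, ≈1.3e−3 for species 2),
because a single power transform cannot make the Poisson-induced λ̂
distribution exactly normal 3.3 standard deviations into the tails; the
more skewed the raw distribution, the larger the residual excess.

*Likelihood-ratio test.* Per species, null (λ1 = λ2 = 1, μ free) against
the alternative freeing the focal λ; 2Δlog L against χ²₁. On neutral
Poisson data the empirical size at nominal 5% is within binomial error
(measured ≈ 0.046–0.049), and the mean statistic ≈ 1.

## Sweep-intensity inversion

λ is mapped to s through the recurrent-sweep model described in the README.
Numerical notes: the upper incomplete gamma at negative shape a = −2c/s is
evaluated through the scaled downward recurrence
G(a) = (G(a+1)/α − e^{−1/α})/a with G seeded from a positive shape via
`gammaincc` — with x = 1/α the factor (αx)^a is exactly 1, which removes
all overflow — and shapes within 1e−6 of an integer or deeper than 60 steps
are delegated to arbitrary precision (mpmath), since the recurrence passes
through a removable 0/0 at integer shapes. Agreement with the
arbitrary-precision reference is ≤ 1e−8 across the tested (c, s, N) grid.
Eq-level choices: the flank average is computed as the printed discrete
per-site sum over one flank of L′ sites (by symmetry identical to averaging
both flanks); h(0) = 0 and h(∞) = 1 are handled as explicit limits (the
finite-c limit of the formula is e^{−1/(2Ns)}, i.e. ≈1 only for large
α = 2Ns). Inversion uses Brent's method on log s over [1e−5, 0.5] after a
numerical monotonicity assertion; λ̂ ≥ 1 returns no solution. When
inverting for a species we use its neutral size N_j from the global fit
(λ is already the *ratio* to the neutral diversity, so the neutral N is the
consistent scale).

## Simulators

*Poisson sampler* — the exact sampling distribution assumed by the
likelihood; used for calibration and recovery experiments.

*Structured-coalescent Monte Carlo* — clean split, no migration, infinite
sites; accumulates branch lengths by JAFS class, so its means are unbiased
estimates of the analytic expectations with per-replicate variance from the
genealogy only (Poisson mutation noise is added only when counts are
requested).

*Wright–Fisher forward simulator* — discrete non-overlapping generations,
diploid individuals, finite-sites biallelic mutation (collisions redrawn),
Poisson crossovers, multiplicative fitness across sites. Directional
selection: heterozygote 1+s, homozygote 1+2s, with a configurable fraction
of new mutations beneficial inside a target region. Overdominance:
heterozygote 1+h·s, homozygote 1+s with h = 2 by default — h > 1 in this
parameterisation is what makes the polymorphism stable; the variant is
inserted at the segment centre at the onset time and the run restarts from
the onset state if it is lost (in the focal species-1 lineage when placed
ancestrally). Populations are initialised at neutral coalescent equilibrium
(an exact stationary sample of all 2N0 haplotypes) followed by a short
forward spin, instead of a long burn-in. Rescaling by Q (sizes and times ÷Q,
rates and s ×Q) preserves the diffusion-scale compounds Nμ, Nρ, Ns and
T/N; it is trusted only while s·Q ≪ 1 (we cap at 0.1).

What the simulations do *not* emulate of real data: mutation-rate and
recombination-rate heterogeneity, linked selection outside the modelled
segment, gene flow after the split, population size change, sequencing or
phasing error, and reference/alignment artefacts. Passing tests therefore
validate the statistical machinery under its own assumptions, not
robustness to those features (masks and the neutral-region protocol exist
precisely to push real data toward the assumptions).

## Problem sizes used in the validation suite

Chosen to keep the full suite within minutes while leaving Monte-Carlo
error well below the tested tolerances: 1e5 coalescent replicates for the
JAFS oracle (n1 = n2 = 4 at 1/50-scaled deep-divergence parameters); 1,000
Poisson windows for demography recovery (plus 4×300-window replicate fits
for the precision comparison); 1e5 Poisson windows for the Box-Cox tail
calibration; 1,000 windows for the LRT size check; and rescaled forward
power experiments (Q = 20 recent-divergence, 10-kb segments, 30 neutral +
15 selected per intensity for positive selection; Q = 40 deep-divergence,
2-kb segments, 20 neutral + 10 per onset for balancing) scored by rank-based
power at matched false-positive rates. Full-scale power replication (200
replicates at N = 10,000–20,000 over ≥ 3.2e5 generations) is a
cluster-scale computation by design.

## Known limitations

* Constant population sizes; no migration; two species only.
* At deep divergence (T_d ≫ 2N) the ancestral size and split time are not
  separately identifiable — the likelihood is flat along T_d + 2N0 — and
  only descendant sizes and that combination are estimable. This is a
  property of the data, not the optimiser; recent divergence resolves it.
* Overlapping sliding windows are correlated; calls are per window, and
  merging significant windows into regions is an optional post-process.
* "Fixed" is defined relative to the sample, not the species; with small
  samples some high-frequency polymorphisms are counted as fixed (the model
  expectations use the same sample-level definition, so the comparison is
  consistent).
* The per-site double-mutation model for ES12′ ignores mutation-rate
  heterogeneity along the window (CpG effects), which is why CpG islands
  should be masked for the demography fit.
* Not applicable to selfing species or genomes without recombination.
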