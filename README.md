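# hkascan

Model-based HKA-type genome scan for **lineage-specific positive selection
and balancing selection** from population genomic data of two closely
related species.

## The problem

Comparative population genomics asks where in the genome natural selection
has acted since two species split. Classical HKA-style tests contrast
within-species polymorphism with between-species divergence, but they
ignore a third, highly informative signal for closely related species:
**shared polymorphism** — ancestral variation still segregating in both
descendants. `hkascan` models all of it jointly.

Each genomic window *l* is summarised by four counts:

* `S1`, `S2` — sites segregating within species 1 / species 2 only,
* `S12` — sites segregating in both species,
* `D` — sites fixed for different alleles in the two samples.

Under a Poisson random-field assumption these are independent Poisson
variables whose means follow from the expected two-species joint allele
frequency spectrum (JAFS) of a split model: an ancestral population of
diploid size *N₀* that divided *T_d* generations ago into descendants of
sizes *N₁* and *N₂*, with per-site mutation rate *μ*. The JAFS decomposes
into "ancient" variation (arising before the split, surviving through the
ancestral-lineage process *g₍n,m₎(T_d)* of each sample) and "new" mutations
on the descendant branches; `S12` additionally receives a recurrent
double-mutation term `E S12′`.

Selection is modelled through two locus-specific scale factors on the
descendant sizes, **λ₁** and **λ₂** (*λN* in all coalescent rates):

* λ < 1 mimics recurrent positive selection (hitchhiking removes linked
  diversity and accelerates fixation — like a smaller population),
* λ > 1 mimics balancing selection (excess diversity and shared
  polymorphism),
* λ = 1 is neutral.

Inference is two-step maximum likelihood: (1) fit the global demography
(*N₀, N₁, N₂, T_d*) genome-wide with λ ≡ 1 and known reference *μ*;
(2) per window, fit (λ₁, λ₂, μ_l) with the demography fixed. Significance
comes either from the genome-wide λ distribution — Box-Cox transformed to
standard normal, windows called at |z| > 3.2905 (one-tailed p = 0.0005;
z < −3.2905 positive, z > +3.2905 balancing) — or from a per-species
likelihood-ratio test against χ²₁.

Finally, λ̂ can be inverted into a **selection intensity** *s* through a
recurrent-sweep hitchhiking model: single-sweep escape probability
`h(c) = (2c/s) α^(−2c/s) Γ(−2c/s, 1/α)` with `α = 2Ns`, sweep arrival rate
`k_h(c) = 2N m_f (1 − h(c))` with `m_f = 2N μ m_s p_f`, and
`λ(s) = (1/L′) Σ_l 1/(1 + k_h(l ρ))`, solved for *s* by bisection.

## Worked example

Simulate 200 neutral 10-kb windows under a recent-divergence history
(N₀ = N₁ = 10,000, N₂ = 20,000, T_d = 40,000 generations, μ = 2.5×10⁻⁸,
20 haplotypes per species), then run the two-step fit and the scan:

```bash
cat > scenario.yaml <<EOF
mode: poisson
model: {N0: 10000, N1: 10000, N2: 20000, Td: 40000, mu_ref: 2.5e-8}
n1: 20
n2: 20
length: 10000
mu: 2.5e-8
loci: 200
EOF
hkascan simulate  --scenario scenario.yaml --seed 3 --out-prefix demo
hkascan fit-global --counts demo.counts.tsv --n1 20 --n2 20 \
                   --init-td 40000 --init-n2 20000 --out demo.globals.json
hkascan scan       --counts demo.counts.tsv --globals demo.globals.json \
                   --n1 20 --n2 20 --out demo.scan.tsv
```

which prints

```
hkascan INFO: N0=9589.2 N1=9920.0 N2=19849.8 Td=40063.3 (loglik -2117.21, converged=True)
hkascan INFO: scanned 200 windows: positive (0, 0), balancing (0, 0) (per species)
```

All four demographic parameters are recovered within ~4% of the generating
values, and — as expected on purely neutral data at the 0.0005 tail
threshold — no window is called selected in either species. The scan table
(`demo.scan.tsv`) carries per window the four counts, the fitted λ₁, λ₂ and
μ_l, the Box-Cox z-scores and one-tailed p-values, and the calls; e.g. the
first window fits λ₁ = 0.758, λ₂ = 1.531 (neutral sampling noise around 1).

`hkascan infer-s --scan demo.scan.tsv --globals demo.globals.json --rho 1e-8
--out demo.s.tsv` appends recurrent-sweep intensity estimates `s_hat` for
windows with λ̂ < 1.

The same pipeline is available as a library (`hkascan.fit_global`,
`hkascan.fit_locus`, `hkascan.boxcox_fit`, `hkascan.classify_windows`,
`hkascan.infer_s`, …), plus simulators used as independent oracles in the
test suite: exact Poisson sampling from the model expectations, a
structured-coalescent Monte Carlo, and a rescalable Wright-Fisher forward
simulator with directional or overdominant selection
(`hkascan.simulate`).

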