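"""Synthetic data generation and independent simulation oracles.

Three generators, in increasing order of realism and cost:

* :func:`sample_counts_poisson` draws the four window summaries directly
  from their model expectations (the exact sampling distribution assumed by
  the likelihood) — used for calibration and estimator-recovery studies.
* :func:`simulate_neutral_coalescent` is a structured-coalescent Monte Carlo
  for the split model (clean split, no migration, infinite sites), an
  independent check of the analytical joint-spectrum expectations.
* :func:`simulate_forward` is a discrete Wright-Fisher forward simulator
  with recombination and directional or overdominant selection, supporting
  the usual diffusion-preserving rescaling (N/Q, s*Q, mu*Q, rho*Q, times/Q)
  so selection experiments run at desk scale.

All generators take an explicit seed and are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .inference import WindowCounts
from .model import DemographicModel, LocusParams, SampleConfig, expected_summaries


# ---------------------------------------------------------------------------
# Poisson sampling from model expectations
# ---------------------------------------------------------------------------

def sample_counts_poisson(model: DemographicModel, cfg: SampleConfig,
                          loci, seed: int) -> list[WindowCounts]:
    """Draw (S1, S2, S12, D) independently Poisson at the model expectations
    for each locus in ``loci`` (a list of LocusParams)."""
    rng = np.random.default_rng(seed)
    out = []
    for i, locus in enumerate(loci):
        q = expected_summaries(cfg, model, locus)
        s1, s2, s12, d = rng.poisson([q.ES1, q.ES2, q.ES12, q.ED])
        length = int(locus.length)
        out.append(WindowCounts(id=f"locus{i}", chrom="sim", start=i * length,
                                end=(i + 1) * length, effective_length=length,
                                S1=int(s1), S2=int(s2), S12=int(s12), D=int(d)))
    return out


# ---------------------------------------------------------------------------
# structured-coalescent Monte Carlo oracle
# ---------------------------------------------------------------------------

def _coalesce_phase(lineages, n_dip, t_max, rng, acc, w1, w2):
    """Coalesce ``lineages`` (list of (i, j) descendant-count pairs) in a
    diploid population of size ``n_dip`` for at most ``t_max`` generations
    (None = until one lineage remains).  Branch lengths are accrued into the
    JAFS-indexed accumulator ``acc`` weighted per class."""
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(2.0 * n_dip / (k * (k - 1) / 2.0))
        if t_max is not None and t + wait > t_max:
            dt = t_max - t
            for i, j in lineages:
                acc[i, j] += dt
            return lineages
        for i, j in lineages:
            acc[i, j] += wait
        t += wait
        a, b = rng.choice(k, size=2, replace=False)
        ia, ja = lineages[a]
        ib, jb = lineages[b]
        merged = (ia + ib, ja + jb)
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (a, b)]
        lineages.append(merged)
    if t_max is not None and lineages:
        i, j = lineages[0]
        acc[i, j] += t_max - t
    return lineages


def simulate_neutral_coalescent(model: DemographicModel, cfg: SampleConfig,
                                locus: LocusParams, reps: int, seed: int,
                                return_counts: bool = False):
    """Monte-Carlo estimate of the expected JAFS under the neutral split
    model (descendant sizes lambda1*N1, lambda2*N2; ancestral N0).

    Returns (jafs_mean, jafs_se) matrices of expected site counts per window
    (infinite-sites: no recurrent-mutation shared polymorphism), and, when
    ``return_counts`` is set, a list of WindowCounts with the four summaries
    Poisson-sampled from each replicate's branch lengths.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = cfg.n1, cfg.n2
    mu_l = locus.mu_l * locus.length
    shape = (n1 + 1, n2 + 1)
    total = np.zeros(shape)
    total_sq = np.zeros(shape)
    counts = []
    mask_s1 = np.zeros(shape, dtype=bool)
    mask_s1[1:n1, 0] = mask_s1[1:n1, n2] = True
    mask_s2 = np.zeros(shape, dtype=bool)
    mask_s2[0, 1:n2] = mask_s2[n1, 1:n2] = True
    mask_s12 = np.zeros(shape, dtype=bool)
    mask_s12[1:n1, 1:n2] = True
    mask_d = np.zeros(shape, dtype=bool)
    mask_d[n1, 0] = mask_d[0, n2] = True
    for r in range(reps):
        acc = np.zeros(shape)
        l1 = _coalesce_phase([(1, 0)] * n1, locus.lambda1 * model.N1,
                             model.Td, rng, acc, n1, n2)
        l2 = _coalesce_phase([(0, 1)] * n2, locus.lambda2 * model.N2,
                             model.Td, rng, acc, n1, n2)
        _coalesce_phase(l1 + l2, model.N0, None, rng, acc, n1, n2)
        acc[n1, n2] = 0.0  # root class: monomorphic, unobservable
        acc[0, 0] = 0.0
        e = mu_l * acc
        total += e
        total_sq += e * e
        if return_counts:
            sites = rng.poisson(e)
            counts.append(WindowCounts(
                id=f"rep{r}", chrom="sim", start=0, end=int(locus.length),
                effective_length=int(locus.length),
                S1=int(sites[mask_s1].sum()), S2=int(sites[mask_s2].sum()),
                S12=int(sites[mask_s12].sum()), D=int(sites[mask_d].sum())))
    mean = total / reps
    var = np.maximum(total_sq / reps - mean * mean, 0.0)
    se = np.sqrt(var / reps)
    # Poisson mutation noise on top of branch-length variance (for tests
    # comparing against Poisson-sampled counts se includes both terms)
    if return_counts:
        return mean, se, counts
    return mean, se


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Selection regime of a simulated segment.

    kind "positive": after ``onset`` generations before present, a fraction
    of new mutations inside ``region`` (defaults to the whole segment) are
    beneficial with heterozygote fitness 1+s, homozygote 1+2s.
    kind "balancing": a single overdominant variant (heterozygote 1+h*s,
    homozygote 1+s) is inserted at the segment centre at ``onset``; the run
    restarts from the onset state if the variant is lost by drift.
    """

    kind: str = "none"
    s: float = 0.0
    fraction_beneficial: float = 0.0
    h: float = 2.0
    onset: float | None = None
    placement: str = "species1"
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "positive", "balancing"):
            raise ValueError(f"unknown selection kind {self.kind!r}")
        if not 0.0 <= self.fraction_beneficial <= 1.0:
            raise ValueError("fraction_beneficial must be in [0, 1]")


@dataclass(frozen=True)
class SimulationScenario:
    """Full specification of one forward-simulated segment."""

    model: DemographicModel
    cfg: SampleConfig
    length: int = 10_000
    mu: float = 2.5e-8
    rho: float = 1e-8
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    ancestral_generations: int | None = None  # default: 4*N0 spin-in
    coalescent_init: bool = True
    seed: int = 0
    max_restarts: int = 500

    def ancestral_span(self) -> int:
        if self.ancestral_generations is not None:
            return int(self.ancestral_generations)
        return int(4 * self.model.N0)

    def validate(self) -> None:
        sel = self.selection
        if sel.kind != "none" and sel.onset is not None:
            if sel.onset > self.model.Td + self.ancestral_span():
                raise ValueError("selection onset precedes the simulated history")


def rescale_scenario(sc: SimulationScenario, q: int) -> SimulationScenario:
    """Diffusion-preserving rescaling by integer factor q: sizes and times
    divided by q, rates and selection multiplied by q."""
    m = sc.model
    for nval in (m.N0, m.N1, m.N2):
        if nval % q:
            raise ValueError("rescaling factor must divide the population sizes")
    model = DemographicModel(m.N0 // q, m.N1 // q, m.N2 // q, m.Td / q,
                             m.mu_ref * q)
    sel = sc.selection
    if sel.kind != "none":
        sel = replace(sel, s=sel.s * q,
                      onset=None if sel.onset is None else sel.onset / q)
    anc = None if sc.ancestral_generations is None else int(sc.ancestral_generations / q)
    return replace(sc, model=model, mu=sc.mu * q, rho=sc.rho * q,
                   selection=sel, ancestral_generations=anc)


@dataclass
class HaplotypeSample:
    """Sampled alignments of the two species over the union of variable
    positions; alleles are 0/1 relative to the known ancestral state."""

    positions: np.ndarray          # strictly increasing site positions
    haplotypes1: np.ndarray        # (n1, S) uint8
    haplotypes2: np.ndarray        # (n2, S) uint8
    length: int


class _VariantLost(Exception):
    pass


class _WFPop:
    """Haplotype-matrix representation of one diploid population."""

    __slots__ = ("geno", "pos", "sel", "fixed", "occupied", "tracked")

    def __init__(self, n_dip: int, positions=None, geno=None):
        self.pos = np.array([] if positions is None else positions, dtype=np.int64)
        self.geno = (np.zeros((2 * n_dip, 0), dtype=np.uint8)
                     if geno is None else geno.astype(np.uint8))
        self.sel = np.zeros(self.pos.size, dtype=float)
        self.fixed: set[int] = set()
        self.occupied: set[int] = set(int(p) for p in self.pos)
        self.tracked: int | None = None  # position of the balancing variant

    @property
    def n_dip(self) -> int:
        return self.geno.shape[0] // 2

    def snapshot(self) -> dict:
        return {"geno": self.geno.copy(), "pos": self.pos.copy(),
                "sel": self.sel.copy(), "fixed": set(self.fixed),
                "occupied": set(self.occupied), "tracked": self.tracked}

    def restore(self, snap: dict) -> None:
        self.geno = snap["geno"].copy()
        self.pos = snap["pos"].copy()
        self.sel = snap["sel"].copy()
        self.fixed = set(snap["fixed"])
        self.occupied = set(snap["occupied"])
        self.tracked = snap["tracked"]


def _fitness(pop: _WFPop, kind: str, h: float) -> np.ndarray | None:
    sel_cols = np.nonzero(pop.sel != 0.0)[0]
    if sel_cols.size == 0:
        return None
    g = (pop.geno[0::2][:, sel_cols].astype(np.int16)
         + pop.geno[1::2][:, sel_cols].astype(np.int16))
    s = pop.sel[sel_cols]
    if kind == "balancing":
        factor = 1.0 + s * h * (g == 1) + s * (g == 2)
    else:  # additive directional: het 1+s, hom 1+2s
        factor = 1.0 + s * g
    w = np.prod(factor, axis=1)
    return w / w.sum()


def _step(pop: _WFPop, rng: np.random.Generator, mu: float, rho: float,
          length: int, sel_active: bool, sel: SelectionSpec,
          target_n: int | None = None) -> None:
    """One non-overlapping Wright-Fisher generation (in place)."""
    n_parent = pop.n_dip
    n_child = n_parent if target_n is None else target_n
    n_gam = 2 * n_child
    p = _fitness(pop, sel.kind, sel.h)
    if p is None:
        parents = rng.integers(0, n_parent, size=n_gam)
    else:
        parents = rng.choice(n_parent, size=n_gam, p=p)
    starts = rng.integers(0, 2, size=n_gam)
    children = pop.geno[2 * parents + starts]
    if children.base is not None:
        children = children.copy()
    # recombination: crossover count per meiosis is Poisson(rho*(length-1))
    n_x = rng.poisson(rho * max(length - 1, 0), size=n_gam)
    for g_idx in np.nonzero(n_x)[0]:
        cuts = np.sort(rng.uniform(0, length, size=n_x[g_idx]))
        parity = (starts[g_idx] + np.searchsorted(cuts, pop.pos, side="right")) % 2
        par = parents[g_idx]
        children[g_idx] = np.where(parity == starts[g_idx],
                                   pop.geno[2 * par + starts[g_idx]],
                                   pop.geno[2 * par + 1 - starts[g_idx]])
    # new mutations (finite sites, biallelic; collisions redrawn in batch)
    n_mut = rng.poisson(n_gam * mu * length)
    if n_mut:
        accepted: list[int] = []
        taken = set()
        for _ in range(100):
            need = n_mut - len(accepted)
            if need <= 0:
                break
            for p_try in rng.integers(0, length, size=need):
                p_try = int(p_try)
                if p_try not in pop.occupied and p_try not in taken:
                    accepted.append(p_try)
                    taken.add(p_try)
        pos_new = np.array(accepted, dtype=np.int64)
        made = pos_new.size
        if made:
            s_new = np.zeros(made)
            if sel_active and sel.kind == "positive" and sel.fraction_beneficial > 0:
                lo, hi = sel.region if sel.region else (0, length)
                hit = ((rng.random(made) < sel.fraction_beneficial)
                       & (pos_new >= lo) & (pos_new < hi))
                s_new[hit] = sel.s
            cols = np.zeros((n_gam, made), dtype=np.uint8)
            cols[rng.integers(0, n_gam, size=made), np.arange(made)] = 1
            children = np.concatenate([children, cols], axis=1)
            pop.pos = np.concatenate([pop.pos, pos_new])
            pop.sel = np.concatenate([pop.sel, s_new])
            pop.occupied.update(int(p) for p in pos_new)
    pop.geno = children
    # fixation / loss bookkeeping
    tot = pop.geno.sum(axis=0)
    lost = tot == 0
    fixed = tot == n_gam
    if pop.tracked is not None:
        t_idx = np.nonzero(pop.pos == pop.tracked)[0]
        if t_idx.size == 0 or lost[t_idx[0]]:
            raise _VariantLost
    if np.any(lost | fixed):
        for p_idx in np.nonzero(fixed)[0]:
            pop.fixed.add(int(pop.pos[p_idx]))
        for p_idx in np.nonzero(lost)[0]:
            pop.occupied.discard(int(pop.pos[p_idx]))
        keep = ~(lost | fixed)
        pop.geno = pop.geno[:, keep]
        pop.pos = pop.pos[keep]
        pop.sel = pop.sel[keep]


def _equilibrium_population(n_dip: int, mu: float, length: int,
                            rng: np.random.Generator) -> _WFPop:
    """Initialise a population at neutral coalescent equilibrium by
    simulating a standard coalescent tree for all 2N haplotypes and
    dropping mutations on it (finite sites, collisions redrawn)."""
    n = 2 * n_dip
    lineages = [[i] for i in range(n)]
    sites: list[tuple[int, list[int]]] = []
    occupied: set[int] = set()
    k = n
    while k > 1:
        wait = rng.exponential(2.0 * n_dip / (k * (k - 1) / 2.0))
        n_mut = rng.poisson(mu * length * wait * k)
        for _ in range(n_mut):
            for _ in range(100):
                pos_try = int(rng.integers(0, length))
                if pos_try not in occupied:
                    break
            else:
                continue
            occupied.add(pos_try)
            carrier = int(rng.integers(0, k))
            sites.append((pos_try, list(lineages[carrier])))
        a, b = rng.choice(k, size=2, replace=False)
        merged = lineages[a] + lineages[b]
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (a, b)]
        lineages.append(merged)
        k -= 1
    pop = _WFPop(n_dip)
    if sites:
        pos = np.array([s[0] for s in sites], dtype=np.int64)
        geno = np.zeros((n, len(sites)), dtype=np.uint8)
        for col, (_, carriers) in enumerate(sites):
            geno[carriers, col] = 1
        pop.pos, pop.geno = pos, geno
        pop.sel = np.zeros(len(sites))
        pop.occupied = occupied
    return pop


def _insert_balancing_variant(pop: _WFPop, sel: SelectionSpec, length: int,
                              rng: np.random.Generator) -> None:
    pos = length // 2
    while pos in pop.occupied:
        pos += 1
        if pos >= length:
            pos = 0
    pop.pos = np.concatenate([pop.pos, [pos]])
    pop.sel = np.concatenate([pop.sel, [sel.s]])
    col = np.zeros((pop.geno.shape[0], 1), dtype=np.uint8)
    col[rng.integers(0, pop.geno.shape[0])] = 1
    pop.geno = np.concatenate([pop.geno, col], axis=1)
    pop.occupied.add(pos)
    pop.tracked = pos


def simulate_forward(scenario: SimulationScenario,
                     rng: np.random.Generator | None = None) -> HaplotypeSample:
    """Run the scenario and return sampled haplotypes from both species."""
    scenario.validate()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m, sel, length = scenario.model, scenario.selection, scenario.length
    td = int(round(m.Td))
    anc_span = scenario.ancestral_span()
    onset = sel.onset if sel.kind != "none" else None
    if onset is None and sel.kind == "positive":
        onset = td  # beneficial input starts at the split by default
    placement_ancestral = sel.kind != "none" and onset is not None and onset > td

    n0 = int(m.N0)
    if scenario.coalescent_init:
        anc = _equilibrium_population(n0, scenario.mu, length, rng)
    else:
        anc = _WFPop(n0)

    def run_epoch(pops, sizes, start_t, end_t):
        """Advance from start_t down to end_t (generations before present)."""
        for t in range(int(start_t), int(end_t), -1):
            for pop, size in zip(pops, sizes):
                active = (sel.kind == "positive" and onset is not None
                          and t <= onset
                          and (placement_ancestral or pop is not anc))
                _step(pop, rng, scenario.mu, scenario.rho, length,
                      active, sel, target_n=size)

    n1_dip, n2_dip = int(m.N1), int(m.N2)

    def split_and_run(start_t: int) -> tuple[_WFPop, _WFPop]:
        """Split the ancestral pool at td and run both species to t=0; the
        split reproduction step itself consumes the generation td -> td-1.
        For an ancestrally placed balancing variant, species 1 is the focal
        lineage whose loss triggers a restart; loss in species 2 merely
        produces a divergent site."""
        pop1, pop2 = _clone_from(anc), _clone_from(anc)
        pop2.tracked = None
        _step(pop1, rng, scenario.mu, scenario.rho, length, False, sel,
              target_n=n1_dip)
        _step(pop2, rng, scenario.mu, scenario.rho, length, False, sel,
              target_n=n2_dip)
        run_epoch([pop1, pop2], [n1_dip, n2_dip], start_t, 0)
        return pop1, pop2

    if sel.kind == "balancing" and placement_ancestral:
        run_epoch([anc], [n0], anc_span + td, onset)
        _insert_balancing_variant(anc, sel, length, rng)
        snap = anc.snapshot()
        for _ in range(scenario.max_restarts):
            try:
                run_epoch([anc], [n0], onset, td)
                pop1, pop2 = split_and_run(td - 1)
                break
            except _VariantLost:
                anc.restore(snap)
        else:
            raise RuntimeError("balancing variant lost in every restart")
    elif sel.kind == "balancing":
        run_epoch([anc], [n0], anc_span + td, td)
        pop1, pop2 = _clone_from(anc), _clone_from(anc)
        _step(pop1, rng, scenario.mu, scenario.rho, length, False, sel,
              target_n=n1_dip)
        _step(pop2, rng, scenario.mu, scenario.rho, length, False, sel,
              target_n=n2_dip)
        run_epoch([pop1, pop2], [n1_dip, n2_dip], td - 1, onset)
        target = pop1 if sel.placement == "species1" else pop2
        _insert_balancing_variant(target, sel, length, rng)
        snap1, snap2 = pop1.snapshot(), pop2.snapshot()
        for _ in range(scenario.max_restarts):
            try:
                run_epoch([pop1, pop2], [n1_dip, n2_dip], onset, 0)
                break
            except _VariantLost:
                pop1.restore(snap1)
                pop2.restore(snap2)
        else:
            raise RuntimeError("balancing variant lost in every restart")
    else:
        run_epoch([anc], [n0], anc_span + td, td)
        pop1, pop2 = split_and_run(td - 1)
    return _sample_haplotypes(pop1, pop2, scenario.cfg, length, rng)


def _clone_from(pop: _WFPop) -> _WFPop:
    new = _WFPop(pop.n_dip)
    new.geno = pop.geno.copy()
    new.pos = pop.pos.copy()
    new.sel = pop.sel.copy()
    new.fixed = set(pop.fixed)
    new.occupied = set(pop.occupied)
    new.tracked = pop.tracked
    return new


def _sample_haplotypes(pop1: _WFPop, pop2: _WFPop, cfg: SampleConfig,
                       length: int, rng: np.random.Generator) -> HaplotypeSample:
    rows1 = rng.choice(2 * pop1.n_dip, size=cfg.n1, replace=False)
    rows2 = rng.choice(2 * pop2.n_dip, size=cfg.n2, replace=False)
    h1 = pop1.geno[rows1]
    h2 = pop2.geno[rows2]
    positions = sorted(
        {int(p) for p, col in zip(pop1.pos, h1.T) if col.any()}
        | {int(p) for p, col in zip(pop2.pos, h2.T) if col.any()}
        | pop1.fixed | pop2.fixed
    )
    pos_arr = np.array(positions, dtype=np.int64)
    out1 = np.zeros((cfg.n1, pos_arr.size), dtype=np.uint8)
    out2 = np.zeros((cfg.n2, pos_arr.size), dtype=np.uint8)
    for pop, samp, out in ((pop1, h1, out1), (pop2, h2, out2)):
        idx = {int(p): c for c, p in enumerate(pop.pos)}
        for col, p in enumerate(positions):
            base = 1 if p in pop.fixed else 0
            if p in idx:
                out[:, col] = samp[:, idx[p]] ^ base
            else:
                out[:, col] = base
    return HaplotypeSample(positions=pos_arr, haplotypes1=out1,
                           haplotypes2=out2, length=length)


def summarize_alignment(hap: HaplotypeSample, window_id: str = "sim",
                        chrom: str = "sim") -> WindowCounts:
    """Classify each variable site of a two-species alignment into the four
    summary categories (monomorphic identical sites are ignored)."""
    n1 = hap.haplotypes1.shape[0]
    n2 = hap.haplotypes2.shape[0]
    c1 = hap.haplotypes1.sum(axis=0)
    c2 = hap.haplotypes2.sum(axis=0)
    seg1 = (c1 > 0) & (c1 < n1)
    seg2 = (c2 > 0) & (c2 < n2)
    fixed_diff = (~seg1) & (~seg2) & (np.where(c1 > 0, 1, 0) != np.where(c2 > 0, 1, 0))
    return WindowCounts(
        id=window_id, chrom=chrom, start=0, end=hap.length,
        effective_length=hap.length,
        S1=int(np.sum(seg1 & ~seg2)), S2=int(np.sum(seg2 & ~seg1)),
        S12=int(np.sum(seg1 & seg2)), D=int(np.sum(fixed_diff)))


# ---------------------------------------------------------------------------
# alignment export (plain-text FASTA / VCF)
# ---------------------------------------------------------------------------

def write_fasta(hap: HaplotypeSample, path: str) -> None:
    """One record per haplotype over the variable positions only, species
    prefix in headers (alleles as A=ancestral / T=derived)."""
    alphabet = np.array(["A", "T"])
    with open(path, "w") as fh:
        for prefix, mat in (("sp1", hap.haplotypes1), ("sp2", hap.haplotypes2)):
            for i, row in enumerate(mat):
                fh.write(f">{prefix}_hap{i}\n")
                fh.write("".join(alphabet[row]) + "\n")


def write_vcf(hap: HaplotypeSample, path: str, sample_map_path: str | None = None,
              chrom: str = "sim") -> None:
    """Haploid-sample VCF over the variable positions plus a two-column
    species map (sample id, species label)."""
    n1 = hap.haplotypes1.shape[0]
    n2 = hap.haplotypes2.shape[0]
    names = [f"sp1_hap{i}" for i in range(n1)] + [f"sp2_hap{i}" for i in range(n2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={hap.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for col, pos in enumerate(hap.positions):
            gts = [str(v) for v in hap.haplotypes1[:, col]] \
                + [str(v) for v in hap.haplotypes2[:, col]]
            fh.write(f"{chrom}\t{int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    if sample_map_path:
        with open(sample_map_path, "w") as fh:
            for name in names:
                fh.write(f"{name}\t{'species1' if name.startswith('sp1') else 'species2'}\n")


def simulate_power_replicate(neutral: SimulationScenario,
                             selected: SimulationScenario,
                             n_neutral: int, seed: int) -> list[WindowCounts]:
    """One replicate of the power-experiment design: ``n_neutral`` neutral
    segments plus one selected segment (the last window returned)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_neutral):
        hap = simulate_forward(replace(neutral, seed=int(rng.integers(2 ** 31))))
        out.append(summarize_alignment(hap, window_id=f"neutral{i}"))
    hap = simulate_forward(replace(selected, seed=int(rng.integers(2 ** 31))))
    out.append(summarize_alignment(hap, window_id="selected"))
    return out
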