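"""Window generation, filtering and data ingestion.

Coordinates are 0-based half-open everywhere internally (BED native; VCF
positions converted on read).  The canonical on-disk exchange format is a
tab-separated counts table with header

    id  chrom  start  end  eff_len  S1  S2  S12  D

where ``eff_len`` is the number of unmasked (callable) bases in the window.
Accessibility/exclusion masks are user-supplied BED files (tandem repeats,
segmental duplications, gaps, structural variants, and — for the neutral
windows used in the demography fit — genes with flanks and CpG islands).
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import GlobalFit, WindowCounts

COUNTS_COLUMNS = ["id", "chrom", "start", "end", "eff_len", "S1", "S2", "S12", "D"]


@dataclass(frozen=True)
class ScanConfig:
    """Windowing, filtering and calling parameters of a genome scan."""

    window_size: int = 10_000
    step: int = 1_000
    min_effective_length: int = 2_000
    min_total_count: int = 50
    mu_ref: float = 2.5e-8
    z_threshold: float = 3.2905
    max_missing: float = 0.0
    mask_paths: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must not exceed the window size")
        if min(self.window_size, self.step) < 1:
            raise ValueError("window size and step must be positive")
        if self.min_effective_length < 0 or self.min_total_count < 0:
            raise ValueError("filter thresholds must be nonnegative")


# ---------------------------------------------------------------------------
# counts TSV round trip
# ---------------------------------------------------------------------------

def write_counts(windows, path) -> None:
    df = pd.DataFrame(
        [(w.id, w.chrom, w.start, w.end, w.effective_length,
          w.S1, w.S2, w.S12, w.D) for w in windows],
        columns=COUNTS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> list[WindowCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table is missing columns: {sorted(missing)}")
    return [
        WindowCounts(id=str(r.id), chrom=str(r.chrom), start=int(r.start),
                     end=int(r.end), effective_length=float(r.eff_len),
                     S1=int(r.S1), S2=int(r.S2), S12=int(r.S12), D=int(r.D))
        for r in df.itertuples()
    ]


def write_globals(fit: GlobalFit, path) -> None:
    with open(path, "w") as fh:
        json.dump({"N0": fit.N0, "N1": fit.N1, "N2": fit.N2, "Td": fit.Td,
                   "mu_ref": fit.mu_ref, "loglik": fit.loglik,
                   "n_iter": fit.n_iter, "converged": fit.converged,
                   "message": fit.message}, fh, indent=2)


def read_globals(path) -> GlobalFit:
    with open(path) as fh:
        d = json.load(fh)
    return GlobalFit(N0=d["N0"], N1=d["N1"], N2=d["N2"], Td=d["Td"],
                     mu_ref=d["mu_ref"], loglik=d.get("loglik", float("nan")),
                     n_iter=d.get("n_iter", 0), converged=d.get("converged", True),
                     message=d.get("message", ""))


# ---------------------------------------------------------------------------
# species map and BED masks
# ---------------------------------------------------------------------------

def read_species_map(path) -> dict[str, str]:
    """Two-column TSV: sample id, species label (exactly two labels)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed species-map line: {line!r}")
            mapping[parts[0]] = parts[1]
    labels = sorted(set(mapping.values()))
    if len(labels) != 2:
        raise ValueError(f"species map must define exactly two labels, got {labels}")
    return mapping


class GenomeMask:
    """Merged exclusion intervals per contig with O(log n) coverage queries."""

    def __init__(self, intervals_by_chrom: dict[str, list[tuple[int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals_by_chrom.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._cum[chrom] = np.concatenate([[0], np.cumsum(ends - starts)])

    @classmethod
    def from_bed_files(cls, paths) -> "GenomeMask":
        ivs: dict[str, list[tuple[int, int]]] = {}
        for path in paths:
            with open(path) as fh:
                for ln, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t") if "\t" in line else line.split()
                    if len(parts) < 3:
                        raise ValueError(f"{path}:{ln}: malformed BED line")
                    try:
                        start, end = int(parts[1]), int(parts[2])
                    except ValueError as exc:
                        raise ValueError(f"{path}:{ln}: malformed BED line") from exc
                    if end < start:
                        raise ValueError(f"{path}:{ln}: end < start")
                    ivs.setdefault(parts[0], []).append((start, end))
        return cls(ivs)

    def masked_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of masked bases overlapping [start, end)."""
        if chrom not in self._starts:
            return 0
        s, e, cum = self._starts[chrom], self._ends[chrom], self._cum[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if lo >= hi:
            return 0
        total = int(cum[hi] - cum[lo])
        total -= max(0, start - int(s[lo]))
        total -= max(0, int(e[hi - 1]) - end)
        return total

    def is_masked(self, chrom: str, pos: int) -> bool:
        if chrom not in self._starts:
            return False
        s = self._starts[chrom]
        i = bisect_right(s, pos) - 1
        return i >= 0 and pos < int(self._ends[chrom][i])


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

_CATEGORIES = ("S1", "S2", "S12", "D")


def _classify(c1: int, n1: int, c2: int, n2: int) -> str | None:
    """Category of a biallelic site from sample ALT-allele counts; fixedness
    is defined relative to the sample.  Polarity (REF vs ALT) is irrelevant."""
    seg1 = 0 < c1 < n1
    seg2 = 0 < c2 < n2
    if seg1 and seg2:
        return "S12"
    if seg1:
        return "S1"
    if seg2:
        return "S2"
    if (c1 > 0) != (c2 > 0):
        return "D"
    return None


def vcf_to_windows(vcf_path, species_map: dict[str, str], cfg: ScanConfig,
                   masks: GenomeMask | None = None,
                   contig_lengths: dict[str, int] | None = None) -> list[WindowCounts]:
    """Summarise a two-species VCF into sliding-window counts.

    Only biallelic SNVs are used; sites overlapping the exclusion masks or
    with missing genotypes above ``cfg.max_missing`` are skipped, and masked
    bases are removed from each window's effective length.  A site is
    "fixed" in a species when all sampled alleles agree; no ancestral-allele
    polarisation is needed.
    """
    from cyvcf2 import VCF

    if masks is None:
        masks = GenomeMask.from_bed_files(cfg.mask_paths)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unassigned = [s for s in samples if s not in species_map]
    if unassigned:
        raise ValueError(f"VCF samples missing from species map: {unassigned}")
    labels = sorted(set(species_map.values()))
    if len(labels) != 2:
        raise ValueError("species map must define exactly two labels")
    sp_of = [labels.index(species_map[s]) for s in samples]

    lengths = dict(contig_lengths or {})
    for cname, clen in zip(vcf.seqnames, vcf.seqlens or []):
        lengths.setdefault(cname, clen)

    sites: dict[str, dict[str, list[int]]] = {}
    max_pos: dict[str, int] = {}
    for v in vcf:
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue  # multi-allelic or non-SNV
        chrom = v.CHROM
        pos0 = v.POS - 1
        if masks.is_masked(chrom, pos0):
            continue
        counts = [0, 0]
        totals = [0, 0]
        n_missing = n_alleles = 0
        for idx, geno in enumerate(v.genotypes):
            alleles = geno[:-1]  # trailing element is the phasing flag
            for a in alleles:
                n_alleles += 1
                if a < 0:
                    n_missing += 1
                else:
                    totals[sp_of[idx]] += 1
                    counts[sp_of[idx]] += int(a != 0)
        if n_alleles == 0 or n_missing / n_alleles > cfg.max_missing:
            continue
        if totals[0] == 0 or totals[1] == 0:
            continue
        cat = _classify(counts[0], totals[0], counts[1], totals[1])
        if cat is None:
            continue
        sites.setdefault(chrom, {c: [] for c in _CATEGORIES})[cat].append(pos0)
        max_pos[chrom] = max(max_pos.get(chrom, 0), pos0)

    chroms = sorted(set(sites) | set(lengths))
    out: list[WindowCounts] = []
    for chrom in chroms:
        clen = lengths.get(chrom)
        if clen is None:
            clen = max_pos.get(chrom, 0) + 1
        by_cat = {c: np.sort(np.asarray(sites.get(chrom, {}).get(c, []), dtype=np.int64))
                  for c in _CATEGORIES}
        for start in range(0, max(clen - cfg.window_size + cfg.step, 1), cfg.step):
            end = min(start + cfg.window_size, clen)
            if end <= start:
                continue
            eff = (end - start) - masks.masked_bases(chrom, start, end)
            if eff <= 0:
                continue
            cat_counts = {
                c: int(np.searchsorted(by_cat[c], end, side="left")
                       - np.searchsorted(by_cat[c], start, side="left"))
                for c in _CATEGORIES
            }
            out.append(WindowCounts(
                id=f"{chrom}:{start}-{end}", chrom=chrom, start=start, end=end,
                effective_length=float(eff), S1=cat_counts["S1"],
                S2=cat_counts["S2"], S12=cat_counts["S12"], D=cat_counts["D"]))
    return out


def filter_windows(windows, cfg: ScanConfig) -> list[WindowCounts]:
    """Retain windows with enough callable sequence and enough information:
    effective length >= min AND S1+S2+S12+D >= min total (strict < excluded)."""
    return [w for w in windows
            if w.effective_length >= cfg.min_effective_length
            and w.total >= cfg.min_total_count]


# ---------------------------------------------------------------------------
# scan output
# ---------------------------------------------------------------------------

def write_scan(windows, fits, calls, path) -> None:
    """Combined per-window scan table (coords, counts, estimates, scores)."""
    by_fit = {f.window_id: f for f in fits}
    by_call = {c.window_id: c for c in calls}
    rows = []
    for w in windows:
        f = by_fit.get(w.id)
        c = by_call.get(w.id)
        if f is None or c is None:
            continue
        rows.append({
            "id": w.id, "chrom": w.chrom, "start": w.start, "end": w.end,
            "eff_len": w.effective_length, "S1": w.S1, "S2": w.S2,
            "S12": w.S12, "D": w.D, "lambda1": f.lambda1, "lambda2": f.lambda2,
            "mu_l": f.mu_l, "loglik": f.loglik, "boundary": f.boundary,
            "z1": c.z1, "z2": c.z2, "p1": c.p1, "p2": c.p2,
            "call1": c.call1, "call2": c.call2,
            "lrt1": c.lrt1, "lrt_p1": c.lrt_p1,
            "lrt2": c.lrt2, "lrt_p2": c.lrt_p2,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
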