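"""Significance assessment for per-window scale-factor estimates.

Two procedures are provided.  The first uses the genome-wide distribution of
the fitted lambda values as an empirical null: the skewed distribution is
mapped onto a standard normal with a one-parameter Box-Cox power transform
(exponent chosen by profile maximum likelihood of normality), and windows
are called at a fixed normal quantile: z < -3.2905 (one-tailed p < 0.0005)
flags recurrent positive selection, z > +3.2905 balancing selection.

The second is a likelihood-ratio test per species: the null fixes
lambda1 = lambda2 = 1 (locus mutation rate free); the alternative frees the
focal species' lambda.  Twice the log-likelihood difference is referred to a
chi-squared distribution with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import boxcox as _boxcox_transform

from .inference import (GlobalFit, LocusFit, SampleConfig, SummaryCalculator,
                        WindowCounts, _LocusFitter)

DEFAULT_Z_THRESHOLD = 3.2905  # one-tailed standard-normal p = 0.0005


@dataclass(frozen=True)
class NormalizationModel:
    """Fitted Box-Cox normalisation of one species' lambda distribution."""

    species: int
    boxcox_lambda: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("post-transform standard deviation must be positive")

    def zscore(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("Box-Cox transform requires positive values")
        return (_boxcox_transform(values, self.boxcox_lambda) - self.mean) / self.sd


@dataclass(frozen=True)
class SelectionCall:
    """Per-window normalised scores, p-values and calls."""

    window_id: str
    z1: float
    z2: float
    p1: float
    p2: float
    call1: str
    call2: str
    lrt1: float | None = None
    lrt_p1: float | None = None
    lrt2: float | None = None
    lrt_p2: float | None = None


def boxcox_fit(values, species: int = 1) -> NormalizationModel:
    """Fit the one-parameter Box-Cox exponent by maximum likelihood of
    normality and standardise the transformed values to mean 0, sd 1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("Box-Cox transform requires positive finite values")
    transformed, lam = stats.boxcox(values)
    sd = float(np.std(transformed))
    if sd == 0.0:
        raise ValueError("degenerate (constant) lambda distribution")
    return NormalizationModel(species=species, boxcox_lambda=float(lam),
                              mean=float(np.mean(transformed)), sd=sd)


def _call(z: float, threshold: float) -> str:
    if z < -threshold:
        return "positive"
    if z > threshold:
        return "balancing"
    return "neutral"


def classify_windows(fits, norm1: NormalizationModel, norm2: NormalizationModel,
                     threshold: float = DEFAULT_Z_THRESHOLD,
                     lrt_results: dict | None = None) -> list[SelectionCall]:
    """Score each per-window fit against the two genome-wide normalisations.

    One-tailed p-values p = Phi(-|z|) are reported per species together with
    the fixed-threshold calls.  ``lrt_results`` may map window id to
    ``(stat1, p1, stat2, p2)`` to carry the likelihood-ratio columns along.
    """
    fits = list(fits)
    z1 = norm1.zscore([f.lambda1 for f in fits])
    z2 = norm2.zscore([f.lambda2 for f in fits])
    out = []
    for f, a, b in zip(fits, z1, z2):
        extra = (lrt_results or {}).get(f.window_id, (None,) * 4)
        out.append(SelectionCall(
            window_id=f.window_id,
            z1=float(a), z2=float(b),
            p1=float(stats.norm.sf(abs(a))), p2=float(stats.norm.sf(abs(b))),
            call1=_call(a, threshold), call2=_call(b, threshold),
            lrt1=extra[0], lrt_p1=extra[1], lrt2=extra[2], lrt_p2=extra[3],
        ))
    return out


def lrt(w: WindowCounts, cfg: SampleConfig, globals_fit: GlobalFit,
        species: int, fitter: "_LocusFitter | None" = None) -> tuple[float, float]:
    """Likelihood-ratio test for selection on one species at one window.

    Returns (statistic, p) with statistic = 2 (lnL_alt - lnL_null) and p from
    chi-squared with 1 df.  A statistic below -1e-6 indicates optimiser
    failure and raises.
    """
    if species not in (1, 2):
        raise ValueError("species must be 1 or 2")
    if fitter is None:
        model = globals_fit.as_model() if isinstance(globals_fit, GlobalFit) else globals_fit
        fitter = _LocusFitter(SummaryCalculator(cfg, model))
    alt = fitter.fit(w, "lambda1_only" if species == 1 else "lambda2_only")
    null = fitter.fit(w, "null")
    stat = 2.0 * (alt.loglik - null.loglik)
    if stat < -1e-6:
        raise RuntimeError(f"negative LRT statistic ({stat:.3g}): optimiser failure")
    stat = max(stat, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def merge_significant_windows(calls, windows, species: int,
                              direction: str = "positive") -> list[tuple[str, int, int]]:
    """Optional post-process: greedy union of overlapping significant windows
    into regions (chrom, start, end)."""
    by_id = {w.id: w for w in windows}
    sig = sorted(
        ((by_id[c.window_id].chrom, by_id[c.window_id].start, by_id[c.window_id].end)
         for c in calls
         if (c.call1 if species == 1 else c.call2) == direction and c.window_id in by_id),
    )
    merged: list[list] = []
    for chrom, start, end in sig:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in the
    scan, which uses the fixed normal threshold)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
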