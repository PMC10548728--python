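"""Two-step Poisson maximum-likelihood inference.

Step one estimates the shared demography (N0, N1, N2, Td) from genome-wide
windows assuming every window is neutral (lambda1 = lambda2 = 1) with a known
reference mutation rate.  Step two, with the demography held fixed, estimates
the per-window scale factors (lambda1, lambda2) and the local mutation rate
mu_l by maximising the product of four independent Poisson likelihoods, one
per summary statistic.

The per-window likelihood surface is evaluated through a cached coefficient
decomposition: for fixed demography every expected summary is
``mu * length * c(lambda1, lambda2)`` plus a ``mu^2``-order recurrent-mutation
term in the shared-polymorphism class, where the ``c`` coefficients depend on
the lambdas only through two small per-species kernel vectors.  This makes a
genome scan with millions of windows tractable while remaining exactly equal
to the direct evaluation through :func:`hkascan.model.expected_summaries`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from . import kernels
from .model import DemographicModel, ExpectedQuad, LocusParams, SampleConfig

EXPECTATION_FLOOR = 1e-12
LAMBDA_BOUNDS = (1e-4, 1e4)
MU_BOUNDS = (1e-12, 1e-4)

_LN_LAM_LO = math.log(LAMBDA_BOUNDS[0])
_LN_LAM_HI = math.log(LAMBDA_BOUNDS[1])


@dataclass(frozen=True)
class WindowCounts:
    """Observed summary counts for one genomic window."""

    id: str
    chrom: str
    start: int
    end: int
    effective_length: float
    S1: int
    S2: int
    S12: int
    D: int

    def __post_init__(self) -> None:
        if self.effective_length > self.end - self.start:
            raise ValueError("effective length exceeds window span")
        if min(self.S1, self.S2, self.S12, self.D) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.S1 + self.S2 + self.S12 + self.D


@dataclass(frozen=True)
class GlobalFit:
    """First-step demography estimate with optimiser diagnostics."""

    N0: float
    N1: float
    N2: float
    Td: float
    mu_ref: float
    loglik: float
    n_iter: int
    converged: bool
    message: str = ""

    def as_model(self) -> DemographicModel:
        return DemographicModel(self.N0, self.N1, self.N2, self.Td, self.mu_ref)


@dataclass(frozen=True)
class LocusFit:
    """Second-step per-window estimate under one hypothesis."""

    window_id: str
    hypothesis: str
    lambda1: float
    lambda2: float
    mu_l: float
    loglik: float
    boundary: bool = False
    degenerate: bool = False


HYPOTHESES = ("full", "lambda1_only", "lambda2_only", "null")


def poisson_loglik(obs: WindowCounts, exp: ExpectedQuad) -> float:
    """Sum of four independent Poisson log-pmfs, obs*ln(e) - e - ln(obs!)."""
    means = np.array([exp.ES1, exp.ES2, exp.ES12, exp.ED], dtype=float)
    if np.any(means < 0):
        raise ValueError("negative expectations are invalid Poisson means")
    means = np.maximum(means, EXPECTATION_FLOOR)
    counts = np.array([obs.S1, obs.S2, obs.S12, obs.D], dtype=float)
    return float(np.sum(counts * np.log(means) - means - gammaln(counts + 1.0)))


class SummaryCalculator:
    """Fast expected-summary evaluator for a fixed demography and sample.

    Decomposition (per site, in units of the locus mutation rate mu):

    ``cS1 = 4*N0*g1' A_S1 g2 + wseg1``, similarly ``cS2``;
    ``cS12 = 4*N0*g1' A_S12 g2``  (+ recurrent term ``mu * wseg1 * wseg2``);
    ``cD  = 4*N0*g1' A_D g2 + wstem1 + wstem2``

    where ``g_j`` is the ancestral-lineage-count distribution of sample j at
    the split (at scaled size lambda_j * N_j), ``wseg_j`` the expected total
    mutation opportunity (generations) on segregating new-site classes and
    ``wstem_j`` the expected stem-branch length between the sample MRCA and
    the split.
    """

    def __init__(self, cfg: SampleConfig, model: DemographicModel):
        self.cfg = cfg
        self.model = model
        self._A = kernels.summary_kernels(cfg.n1, cfg.n2)
        self._M1 = kernels.new_site_matrix(cfg.n1)
        self._M2 = kernels.new_site_matrix(cfg.n2)

    def species_features(self, species: int, lam) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(G, wseg, wstem) for an array of lambda values; G has shape
        (len(lam), n_species)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        n = self.cfg.n1 if species == 1 else self.cfg.n2
        nsize = self.model.N1 if species == 1 else self.model.N2
        msum = self._M1.sum(axis=0) if species == 1 else self._M2.sum(axis=0)
        tau = self.model.Td / (2.0 * lam * nsize)
        g, w = kernels.lineage_kernel(n, tau)  # (n, len(lam))
        w_gen = (2.0 * nsize * lam)[None, :] * w
        wseg = msum @ w_gen if n >= 2 else np.zeros(lam.size)
        wstem = w_gen[0]
        return g.T.copy(), wseg, wstem

    def coefficients(self, lam1, lam2, pairwise: bool = False):
        """Per-site coefficients (cS1, cS2, cS12, cD, r12) in units of mu;
        the recurrent shared-polymorphism term is mu^2 * r12 per site.

        With ``pairwise=True`` lam1 and lam2 index a full grid and all
        outputs have shape (len(lam1), len(lam2)); otherwise they are
        broadcast elementwise.
        """
        g1, wseg1, wstem1 = self.species_features(1, lam1)
        g2, wseg2, wstem2 = self.species_features(2, lam2)
        t0 = 4.0 * self.model.N0
        if pairwise:
            q = {k: t0 * (g1 @ a @ g2.T) for k, a in self._A.items()}
            cs1 = q["S1"] + wseg1[:, None]
            cs2 = q["S2"] + wseg2[None, :]
            cs12 = q["S12"]
            cd = q["D"] + wstem1[:, None] + wstem2[None, :]
            r12 = wseg1[:, None] * wseg2[None, :]
        else:
            q = {k: t0 * np.einsum("im,mn,in->i", g1, a, g2) for k, a in self._A.items()}
            cs1 = q["S1"] + wseg1
            cs2 = q["S2"] + wseg2
            cs12 = q["S12"]
            cd = q["D"] + wstem1 + wstem2
            r12 = wseg1 * wseg2
        return cs1, cs2, cs12, cd, r12

    def expected_quad(self, lam1: float, lam2: float, mu: float,
                      length: float) -> ExpectedQuad:
        cs1, cs2, cs12, cd, r12 = self.coefficients([lam1], [lam2])
        es12p = mu * mu * length * float(r12[0])
        return ExpectedQuad(
            ES1=mu * length * float(cs1[0]),
            ES2=mu * length * float(cs2[0]),
            ES12=mu * length * float(cs12[0]) + es12p,
            ED=mu * length * float(cd[0]),
            ES12_recurrent=es12p,
        )


def _profile_mu(counts: tuple[float, float, float, float], length: float,
                cs1, cs2, cs12, cd, r12):
    """Profile out mu for fixed lambdas (vectorised over coefficient arrays).

    Returns (mu_hat, profile_loglik) maximising
    sum_cat S_cat ln(E_cat) - E_cat with E linear in mu except the
    recurrent shared-polymorphism term, quadratic in mu.
    """
    s1, s2, s12, d = counts
    lin = s1 + s2 + d
    tot = lin + s12
    csum = cs1 + cs2 + cs12 + cd
    shape = np.broadcast(cs1, r12).shape
    if tot == 0:
        mu = np.full(shape, MU_BOUNDS[0])
    else:
        # Newton in u = ln(mu) on x*dl/dx; start from the linearised MLE
        mu = tot / (length * np.maximum(csum, EXPECTATION_FLOOR))
        mu = np.clip(mu, MU_BOUNDS[0], MU_BOUNDS[1])
        u = np.log(mu)
        for _ in range(8):
            x = np.exp(u)
            denom = np.maximum(cs12 + x * r12, EXPECTATION_FLOOR)
            gval = lin + s12 * (cs12 + 2.0 * x * r12) / denom \
                - x * length * csum - 2.0 * x * x * length * r12
            gder = s12 * x * r12 * cs12 / (denom * denom) \
                - x * length * csum - 4.0 * x * x * length * r12
            gder = np.where(np.abs(gder) < 1e-300, -1.0, gder)
            step = np.clip(gval / gder, -2.0, 2.0)
            u = u - step
        mu = np.clip(np.exp(u), MU_BOUNDS[0], MU_BOUNDS[1])
    e1 = np.maximum(mu * length * cs1, EXPECTATION_FLOOR)
    e2 = np.maximum(mu * length * cs2, EXPECTATION_FLOOR)
    e12 = np.maximum(mu * length * (cs12 + mu * r12), EXPECTATION_FLOOR)
    ed = np.maximum(mu * length * cd, EXPECTATION_FLOOR)
    ll = (s1 * np.log(e1) + s2 * np.log(e2) + s12 * np.log(e12) + d * np.log(ed)
          - e1 - e2 - e12 - ed)
    ll = ll - float(gammaln(s1 + 1) + gammaln(s2 + 1) + gammaln(s12 + 1) + gammaln(d + 1))
    return mu, ll


class _LocusFitter:
    """Hierarchical grid optimiser over (lambda1, lambda2) with mu profiled.

    A shared coarse log-lambda grid is refined per window by successive
    10-fold zooms; the evaluation path is fully deterministic, so repeated
    fits of the same window are bitwise identical.
    """

    COARSE_POINTS = 33
    ZOOM_POINTS = 15
    ZOOM_STAGES = 3

    def __init__(self, calc: SummaryCalculator):
        self.calc = calc
        self.base_grid = np.linspace(_LN_LAM_LO, _LN_LAM_HI, self.COARSE_POINTS)
        lam = np.exp(self.base_grid)
        self._coarse = {
            "pair": calc.coefficients(lam, lam, pairwise=True),
            "lam": lam,
        }
        one = np.array([1.0])
        g1 = calc.coefficients(lam, one, pairwise=True)
        g2 = calc.coefficients(one, lam, pairwise=True)
        self._coarse1 = tuple(a[:, 0] for a in g1)
        self._coarse2 = tuple(a[0, :] for a in g2)
        self._null = tuple(float(a[0]) for a in calc.coefficients(one, one))

    # -- 2-D (full hypothesis) ------------------------------------------------
    def _fit_full(self, counts, length):
        cs = self._coarse["pair"]
        _, ll = _profile_mu(counts, length, *cs)
        idx = np.unravel_index(int(np.argmax(ll)), ll.shape)
        u1, u2 = self.base_grid[idx[0]], self.base_grid[idx[1]]
        step = self.base_grid[1] - self.base_grid[0]
        for _ in range(self.ZOOM_STAGES):
            grid1 = np.clip(u1 + np.linspace(-step, step, self.ZOOM_POINTS),
                            _LN_LAM_LO, _LN_LAM_HI)
            grid2 = np.clip(u2 + np.linspace(-step, step, self.ZOOM_POINTS),
                            _LN_LAM_LO, _LN_LAM_HI)
            cs = self.calc.coefficients(np.exp(grid1), np.exp(grid2), pairwise=True)
            mu, ll = _profile_mu(counts, length, *cs)
            idx = np.unravel_index(int(np.argmax(ll)), ll.shape)
            u1, u2 = grid1[idx[0]], grid2[idx[1]]
            step = 2.0 * step / (self.ZOOM_POINTS - 1)
        return u1, u2, float(mu[idx]), float(ll[idx])

    # -- 1-D (single-lambda hypotheses) --------------------------------------
    def _fit_one(self, counts, length, species: int):
        cs = self._coarse1 if species == 1 else self._coarse2
        _, ll = _profile_mu(counts, length, *cs)
        i = int(np.argmax(ll))
        u = self.base_grid[i]
        step = self.base_grid[1] - self.base_grid[0]
        one = np.array([1.0])
        for _ in range(self.ZOOM_STAGES):
            grid = np.clip(u + np.linspace(-step, step, self.ZOOM_POINTS),
                           _LN_LAM_LO, _LN_LAM_HI)
            if species == 1:
                cs = self.calc.coefficients(np.exp(grid), one, pairwise=True)
                cs = tuple(a[:, 0] for a in cs)
            else:
                cs = self.calc.coefficients(one, np.exp(grid), pairwise=True)
                cs = tuple(a[0, :] for a in cs)
            mu, ll = _profile_mu(counts, length, *cs)
            i = int(np.argmax(ll))
            u = grid[i]
            step = 2.0 * step / (self.ZOOM_POINTS - 1)
        return u, float(mu[i]), float(ll[i])

    def fit(self, w: WindowCounts, hypothesis: str, polish: bool = True) -> LocusFit:
        counts = (float(w.S1), float(w.S2), float(w.S12), float(w.D))
        length = float(w.effective_length)
        degenerate = w.total == 0
        if hypothesis == "full":
            u1, u2, mu, ll = self._fit_full(counts, length)
            free_u = [u1, u2]
            unpack = lambda p: (math.exp(p[0]), math.exp(p[1]))
        elif hypothesis == "lambda1_only":
            u1, mu, ll = self._fit_one(counts, length, 1)
            free_u = [u1]
            unpack = lambda p: (math.exp(p[0]), 1.0)
        elif hypothesis == "lambda2_only":
            u2, mu, ll = self._fit_one(counts, length, 2)
            free_u = [u2]
            unpack = lambda p: (1.0, math.exp(p[0]))
        elif hypothesis == "null":
            mu_arr, ll_arr = _profile_mu(counts, length,
                                         *[np.asarray([v]) for v in self._null])
            mu, ll = float(mu_arr[0]), float(ll_arr[0])
            free_u = []
            unpack = lambda p: (1.0, 1.0)
        else:
            raise ValueError(f"unknown hypothesis {hypothesis!r}")

        l1, l2 = unpack(free_u) if free_u else (1.0, 1.0)
        mu_hat = mu

        if polish and free_u and not degenerate:
            def nll(p):
                pl1, pl2 = unpack(p)
                if not (LAMBDA_BOUNDS[0] <= pl1 <= LAMBDA_BOUNDS[1]
                        and LAMBDA_BOUNDS[0] <= pl2 <= LAMBDA_BOUNDS[1]):
                    return 1e12
                cs = self.calc.coefficients([pl1], [pl2])
                _, llv = _profile_mu(counts, length,
                                     *[np.asarray([float(a[0])]) for a in cs])
                return -float(llv[0])

            res = minimize(nll, np.array(free_u), method="Nelder-Mead",
                           options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 400})
            if -res.fun > ll:
                ll = -res.fun
                l1, l2 = unpack(res.x)
                cs = self.calc.coefficients([l1], [l2])
                mu_arr, _ = _profile_mu(counts, length,
                                        *[np.asarray([float(a[0])]) for a in cs])
                mu_hat = float(mu_arr[0])
        eps = 1e-9
        boundary = (
            min(abs(math.log(l1) - _LN_LAM_LO), abs(math.log(l1) - _LN_LAM_HI)) < eps
            and hypothesis in ("full", "lambda1_only")
        ) or (
            min(abs(math.log(l2) - _LN_LAM_LO), abs(math.log(l2) - _LN_LAM_HI)) < eps
            and hypothesis in ("full", "lambda2_only")
        ) or mu_hat <= MU_BOUNDS[0] or mu_hat >= MU_BOUNDS[1]
        return LocusFit(window_id=w.id, hypothesis=hypothesis, lambda1=l1,
                        lambda2=l2, mu_l=mu_hat, loglik=ll,
                        boundary=bool(boundary), degenerate=degenerate)


def fit_locus(w: WindowCounts, cfg: SampleConfig, globals_fit: GlobalFit | DemographicModel,
              hypothesis: str = "full", calc: SummaryCalculator | None = None,
              polish: bool = True) -> LocusFit:
    """Maximum-likelihood fit of one window under the given hypothesis.

    ``full`` frees (lambda1, lambda2, mu_l); ``lambda1_only`` fixes
    lambda2 = 1; ``lambda2_only`` symmetric; ``null`` frees mu_l only.
    """
    model = globals_fit.as_model() if isinstance(globals_fit, GlobalFit) else globals_fit
    if calc is None:
        calc = SummaryCalculator(cfg, model)
    return _LocusFitter(calc).fit(w, hypothesis, polish=polish)


def fit_loci(windows, cfg: SampleConfig, globals_fit, hypothesis: str = "full",
             polish: bool = False) -> list[LocusFit]:
    """Fit many windows sharing one demography (shared kernel caches)."""
    model = globals_fit.as_model() if isinstance(globals_fit, GlobalFit) else globals_fit
    fitter = _LocusFitter(SummaryCalculator(cfg, model))
    return [fitter.fit(w, hypothesis, polish=polish) for w in windows]


_GLOBAL_BOUNDS = {"N": (10.0, 1e8), "Td": (1.0, 1e9)}


def fit_global(loci, cfg: SampleConfig, mu_ref: float,
               init: DemographicModel, bounds: dict | None = None,
               n_starts: int = 3) -> GlobalFit:
    """First-step demography fit on (pre-filtered, putatively neutral) windows.

    All windows share lambda1 = lambda2 = 1 and mutation rate mu_ref, so the
    Poisson likelihood depends on the data only through the total counts and
    total effective length; the fit is therefore exactly invariant to the
    order of the input windows.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("no loci provided")
    bnd = dict(_GLOBAL_BOUNDS)
    if bounds:
        bnd.update(bounds)
    tot = np.array([sum(w.S1 for w in loci), sum(w.S2 for w in loci),
                    sum(w.S12 for w in loci), sum(w.D for w in loci)], dtype=float)
    tot_len = math.fsum(w.effective_length for w in loci)
    const = math.fsum(
        s * math.log(w.effective_length) - float(gammaln(s + 1))
        for w in loci
        for s in (w.S1, w.S2, w.S12, w.D)
        if w.effective_length > 0
    )
    ln_n_lo, ln_n_hi = math.log(bnd["N"][0]), math.log(bnd["N"][1])
    ln_t_lo, ln_t_hi = math.log(bnd["Td"][0]), math.log(bnd["Td"][1])

    def neg_loglik(p: np.ndarray) -> float:
        if not np.all(np.isfinite(p)):
            return 1e15
        if (np.any(p[:3] < ln_n_lo) or np.any(p[:3] > ln_n_hi)
                or p[3] < ln_t_lo or p[3] > ln_t_hi):
            return 1e15
        n0, n1, n2, td = np.exp(p)
        calc = SummaryCalculator(cfg, DemographicModel(n0, n1, n2, td, mu_ref))
        cs1, cs2, cs12, cd, r12 = (float(a[0]) for a in calc.coefficients([1.0], [1.0]))
        q = np.array([mu_ref * cs1, mu_ref * cs2,
                      mu_ref * cs12 + mu_ref ** 2 * r12, mu_ref * cd])
        q = np.maximum(q, EXPECTATION_FLOOR)
        return -float(np.sum(tot * np.log(q)) - float(np.sum(q)) * tot_len)

    p0 = np.log([init.N0, init.N1, init.N2, init.Td])
    best = None
    n_iter = 0
    ok = False
    msg = []
    for mult in (1.0, 0.5, 1.5)[:n_starts]:
        res = minimize(neg_loglik, p0 + math.log(mult), method="Nelder-Mead",
                       options={"fatol": 1e-8, "xatol": 1e-7,
                                "maxiter": 5000, "maxfev": 8000})
        n_iter += res.nit
        ok = ok or bool(res.success)
        msg.append(res.message)
        if best is None or res.fun < best.fun:
            best = res
    if not ok:
        warnings.warn("global demography fit did not report convergence: "
                      + "; ".join(map(str, msg)))
    n0, n1, n2, td = np.exp(best.x)
    return GlobalFit(N0=float(n0), N1=float(n1), N2=float(n2), Td=float(td),
                     mu_ref=mu_ref, loglik=-best.fun + const, n_iter=int(n_iter),
                     converged=ok, message=str(best.message))
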