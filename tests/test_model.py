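"""Unit and oracle tests for the joint-spectrum expectations."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.special import comb

from hkascan import (DemographicModel, LocusParams, SampleConfig,
                     ancestral_afs, ancestral_split_prob, cond_sojourn_time,
                     expected_jafs, expected_summaries, jafs_ancient, jafs_new,
                     lineage_dist, polya_subtend, recurrent_shared)
from hkascan import kernels
from hkascan.model import _cond_sojourn_quad


class TestLineageDist:
    def test_point_mass_at_time_zero(self):
        g = lineage_dist(7, 0.0, 1000)
        assert g[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(g[:-1] < 1e-12)

    def test_two_lineages_closed_form(self):
        # P(no coalescence) = exp(-T / 2N); at T = 2N ln 2 both outcomes 1/2
        n_dip = 500.0
        g = lineage_dist(2, 2 * n_dip * np.log(2.0), n_dip)
        assert g == pytest.approx([0.5, 0.5], abs=1e-10)

    @pytest.mark.parametrize("tau", [0.01, 0.1, 0.5, 1.0, 3.0])
    def test_matches_ode_oracle(self, tau):
        """Independent oracle: integrate the pure-death Kolmogorov equations."""
        n = 6

        def rhs(_, p):
            out = np.zeros(n)
            for k in range(1, n + 1):
                beta = k * (k - 1) / 2.0
                out[k - 1] -= beta * p[k - 1]
                if k > 1:
                    out[k - 2] += beta * p[k - 1]
            return out

        p0 = np.zeros(n)
        p0[-1] = 1.0
        sol = solve_ivp(rhs, (0, tau), p0, rtol=1e-10, atol=1e-12)
        assert lineage_dist(n, tau * 2 * 1000, 1000) == pytest.approx(
            sol.y[:, -1], abs=1e-8)

    @given(n=st.integers(2, 25), tau=st.floats(1e-4, 20.0))
    def test_distribution_sums_to_one(self, n, tau):
        g = lineage_dist(n, tau * 2000.0, 1000.0)
        assert np.all(g >= 0)
        assert np.sum(g) == pytest.approx(1.0, abs=1e-10)

    def test_spectral_matches_expm(self):
        for n in (3, 10, 20, 25):
            for tau in (1e-4, 0.05, 0.8, 5.0, 20.0):
                g_s, w_s = kernels.lineage_kernel(n, tau)
                g_e, w_e = kernels.lineage_kernel_expm(n, tau)
                assert g_s == pytest.approx(g_e, abs=5e-10)
                assert w_s == pytest.approx(w_e, abs=5e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            lineage_dist(4, -1.0, 100)
        with pytest.raises(ValueError):
            lineage_dist(4, np.inf, 100)


class TestPolyaSubtend:
    def test_identity_when_all_ancestors_sampled(self):
        p = polya_subtend(6, 6, 4)
        assert p[4] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_two_ancestor_symmetry(self):
        p = polya_subtend(3, 2, 1)
        assert p[1] == pytest.approx(0.5)
        assert p[2] == pytest.approx(0.5)

    def test_matches_composition_enumeration(self):
        """Oracle: block sizes of m ancestors are uniform over compositions
        of n into m positive parts; enumerate all of them."""
        n, m, k = 8, 3, 2
        hits = {}
        total = 0
        for cuts in itertools.combinations(range(1, n), m - 1):
            sizes = np.diff([0, *cuts, n])
            total += 1
            i = int(sizes[:k].sum())
            hits[i] = hits.get(i, 0) + 1
        p = polya_subtend(n, m, k)
        for i in range(n + 1):
            assert p[i] == pytest.approx(hits.get(i, 0) / total, abs=1e-12)

    @given(st.integers(2, 15), st.data())
    def test_normalised(self, n, data):
        m = data.draw(st.integers(1, n))
        k = data.draw(st.integers(1, m))
        assert polya_subtend(n, m, k).sum() == pytest.approx(1.0, abs=1e-10)

    def test_rejects_inadmissible(self):
        with pytest.raises(ValueError):
            polya_subtend(5, 3, 4)
        with pytest.raises(ValueError):
            polya_subtend(3, 4, 1)


class TestAncestralSplit:
    def test_single_carrier_symmetry(self):
        assert ancestral_split_prob(1, 0, 1, 1) == pytest.approx(0.5)

    def test_normalisation_at_fixed_total(self):
        m1, m2, K = 4, 3, 3
        tot = sum(ancestral_split_prob(k1, K - k1, m1, m2)
                  for k1 in range(max(0, K - m2), min(m1, K) + 1))
        assert tot == pytest.approx(1.0, abs=1e-12)

    def test_matches_subset_enumeration(self):
        # choose 3 carriers among 7 labelled lineages (4 in species 1's set)
        m1, m2, k1, k2 = 4, 3, 2, 1
        lineages = ["a"] * m1 + ["b"] * m2
        count = sum(1 for sub in itertools.combinations(range(m1 + m2), k1 + k2)
                    if sum(lineages[i] == "a" for i in sub) == k1)
        expect = count / comb(m1 + m2, k1 + k2)
        assert ancestral_split_prob(k1, k2, m1, m2) == pytest.approx(expect)

    def test_rejects_inadmissible(self):
        with pytest.raises(ValueError):
            ancestral_split_prob(0, 0, 2, 2)
        with pytest.raises(ValueError):
            ancestral_split_prob(3, 0, 2, 2)


class TestAncestralAFS:
    def test_equilibrium_spectrum_values(self):
        # theta0 / k with theta0 = 4 N0 mu (diploid equilibrium spectrum)
        assert ancestral_afs(1, 10_000, 2.5e-8) == pytest.approx(1.0e-3)
        assert ancestral_afs(2, 10_000, 2.5e-8) == pytest.approx(
            ancestral_afs(1, 10_000, 2.5e-8) / 2)

    def test_matches_coalescent_monte_carlo(self):
        """Oracle: frequency spectrum of a 5-sample coalescent simulation."""
        rng = np.random.default_rng(99)
        n, n_dip, mu = 5, 1000.0, 1e-5
        reps = 40_000
        acc = np.zeros(n)
        for _ in range(reps):
            lineages = [1] * n
            while len(lineages) > 1:
                k = len(lineages)
                wait = rng.exponential(2 * n_dip / (k * (k - 1) / 2))
                for size in lineages:
                    acc[size - 1] += wait
                a, b = rng.choice(k, 2, replace=False)
                merged = lineages[a] + lineages[b]
                lineages = [s for i, s in enumerate(lineages) if i not in (a, b)]
                lineages.append(merged)
            # the root class (size n) is monomorphic and unobservable
        mc = mu * acc[: n - 1] / reps
        for k in range(1, n):
            assert mc[k - 1] == pytest.approx(ancestral_afs(k, n_dip, mu),
                                              rel=0.05)

    def test_rejects_zero_count(self):
        with pytest.raises(ValueError):
            ancestral_afs(0, 100, 1e-8)


class TestCondSojourn:
    def test_sojourns_partition_the_interval(self):
        n, m, t, n_dip = 8, 2, 9000.0, 1500.0
        total = sum(cond_sojourn_time(n, m, k, t, n_dip) for k in range(m, n + 1))
        assert total == pytest.approx(t, rel=1e-6)

    def test_unconditional_pair_coalescent_time(self):
        # E(T_2) for two lineages, unconstrained: 2N generations
        n_dip = 700.0
        t = 200 * n_dip  # effectively infinite
        assert cond_sojourn_time(2, 1, 2, t, n_dip) == pytest.approx(
            2 * n_dip, rel=1e-4)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_quadrature(self, k):
        got = cond_sojourn_time(6, 3, k, 5000.0, 1000.0)
        want = _cond_sojourn_quad(6, 3, k, 5000.0, 1000.0)
        assert got == pytest.approx(want, rel=1e-7)

    def test_impossible_conditioning_raises(self):
        with pytest.raises(ValueError):
            cond_sojourn_time(6, 3, 4, 0.0, 1000.0)  # m < n impossible at T=0


class TestJAFS:
    def test_ancient_vanishes_at_deep_divergence(self, locus10kb):
        model = DemographicModel(1e4, 1e4, 2e4, 2e7, 2.5e-8)
        e = jafs_ancient(SampleConfig(4, 4), model, locus10kb)
        assert e[1:4, 1:4].max() < 1e-12

    def test_split_time_zero_equals_hypergeometric_pooled_spectrum(self):
        """At Td = 0 the two samples are one panmictic sample of n1+n2: the
        joint spectrum is theta0/k split hypergeometrically."""
        n1 = n2 = 4
        cfg = SampleConfig(n1, n2)
        model = DemographicModel(5e3, 1e4, 1e4, 0.0, 2.5e-8)
        locus = LocusParams(mu_l=2.5e-8, length=1e4)
        e = expected_jafs(cfg, model, locus)
        theta0 = 4 * model.N0 * locus.mu_l * locus.length
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                if (i, j) in ((0, 0), (n1, n2)):
                    continue
                want = (theta0 / (i + j)
                        * comb(n1, i) * comb(n2, j) / comb(n1 + n2, i + j))
                assert e[i, j] == pytest.approx(want, rel=1e-9)

    def test_new_sites_zero_without_time(self, locus10kb):
        nu = jafs_new(6, 1e4, locus10kb, 0.0)
        assert np.all(nu == 0)

    def test_new_sites_reach_equilibrium_spectrum(self):
        # deep Td: segregating classes approach 4*N*mu*L/i
        n, n_dip = 6, 1000.0
        locus = LocusParams(mu_l=1e-8, length=1e4)
        nu = jafs_new(n, n_dip, locus, 500 * n_dip)
        base = 4 * n_dip * locus.mu_l * locus.length
        for i in range(1, n):
            assert nu[i - 1] == pytest.approx(base / i, rel=1e-5)

    def test_transposition_symmetry(self, locus10kb):
        cfg = SampleConfig(5, 3)
        m = DemographicModel(8e3, 1e4, 2e4, 5e4, 2.5e-8)
        m_swapped = DemographicModel(8e3, 2e4, 1e4, 5e4, 2.5e-8)
        locus = LocusParams(lambda1=0.5, lambda2=2.0, mu_l=2.5e-8, length=1e4)
        locus_swapped = LocusParams(lambda1=2.0, lambda2=0.5, mu_l=2.5e-8, length=1e4)
        e = expected_jafs(cfg, m, locus)
        et = expected_jafs(SampleConfig(3, 5), m_swapped, locus_swapped)
        assert np.allclose(e, et.T, rtol=0, atol=1e-12)

    def test_margins_exceed_new_component(self, scenario2, locus10kb):
        cfg = SampleConfig(6, 6)
        e = expected_jafs(cfg, scenario2, locus10kb)
        nu1 = jafs_new(6, scenario2.N1, locus10kb, scenario2.Td)
        assert np.all(e[1:6, 0] >= nu1[:5] - 1e-12)


class TestSummaries:
    def test_pairwise_divergence_closed_form(self):
        """ED/L = 2 mu (Td + 2 N0) for one sequence per species."""
        cfg = SampleConfig(1, 1)
        for n0, n1, n2, td, mu in [(1e4, 1e4, 2e4, 2e5, 2.5e-8),
                                   (5e3, 2e4, 1e4, 4e4, 1e-8),
                                   (200, 200, 400, 4e3, 1.25e-6)]:
            model = DemographicModel(n0, n1, n2, td, mu)
            q = expected_summaries(cfg, model, LocusParams(mu_l=mu, length=1e4))
            assert q.ED / 1e4 == pytest.approx(2 * mu * (td + 2 * n0), rel=1e-6)

    def test_lambda1_monotonicity(self, scenario2):
        """Shrinking species 1 (recurrent sweeps) lowers its polymorphism and
        raises divergence."""
        cfg = SampleConfig(10, 10)
        lam_grid = [0.1, 0.25, 0.5, 1.0, 2.0]
        quads = [expected_summaries(cfg, scenario2,
                                    LocusParams(lambda1=l, mu_l=2.5e-8, length=1e4))
                 for l in lam_grid]
        es1 = [q.ES1 for q in quads]
        ed = [q.ED for q in quads]
        assert np.all(np.diff(es1) > 0)   # ES1 increases with lambda1
        assert np.all(np.diff(ed) < 0)    # ED decreases with lambda1

    def test_recurrent_shared_term(self, scenario1):
        cfg = SampleConfig(8, 8)
        zero = recurrent_shared(cfg, DemographicModel(1e4, 1e4, 2e4, 0.0, 2.5e-8),
                                LocusParams(mu_l=2.5e-8, length=1e4))
        assert zero == 0.0
        r1 = recurrent_shared(cfg, scenario1, LocusParams(mu_l=1e-8, length=1e4))
        r2 = recurrent_shared(cfg, scenario1, LocusParams(mu_l=2e-8, length=1e4))
        assert r2 == pytest.approx(4 * r1, rel=1e-9)  # quadratic in mu

    def test_recurrent_dominates_ancient_sharing_at_deep_split(self, scenario1):
        cfg = SampleConfig(20, 20)
        q = expected_summaries(cfg, scenario1, LocusParams(mu_l=2.5e-8, length=1e4))
        assert q.ES12_recurrent <= q.ES12
        ancient = q.ES12 - q.ES12_recurrent
        assert q.ES12_recurrent > 10 * ancient  # tau1 = 10: sharing is recurrent
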