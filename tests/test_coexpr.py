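"""WGCNA-style spatial co-expression modules."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import cortexdem as cd
from cortexdem.coexpr import (
    _scale_free_fit,
    compute_tom,
    cut_modules,
    gene_correlation,
    pick_soft_power,
    soft_adjacency,
)
from cortexdem.dem import DEMLibrary


def _library(surface, Z, genes=None):
    return DEMLibrary(
        gene_ids=genes or [f"g{i}" for i in range(Z.shape[0])], z=Z, surface=surface
    )


@pytest.fixture(scope="module")
def planted(ico3):
    truth = cd.make_truth(
        ico3, n_modules=5, genes_per_module=100, n_boundary_genes=0,
        n_noise_genes=500, field_fwhm_mm=20.0, loading=0.8, seed=1,
    )
    lib = _library(ico3, truth.expr_truth, list(truth.gene_ids))
    return truth, lib


class TestSoftPower:
    def test_power_law_network_reaches_target(self):
        # hub structure: r_ij = 2 u_i u_j - 1 with heavy-tailed u gives
        # power-law soft connectivity
        rng = np.random.default_rng(0)
        u = rng.pareto(2.0, 300) + 0.05
        u = u / u.max()
        r = 2 * np.outer(u, u) - 1
        np.fill_diagonal(r, 1.0)
        power, fits, reached = pick_soft_power(np.clip(r, -1, 1))
        assert reached and fits[power] > 0.8

    def test_structureless_correlation_warns(self):
        rng = np.random.default_rng(1)
        r = 0.01 * rng.standard_normal((50, 50))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        _, _, reached = pick_soft_power(np.clip(r, -1, 1))
        assert not reached

    def test_fit_table_matches_recomputation(self, planted):
        _, lib = planted
        corr = gene_correlation(lib)
        _, fits, _ = pick_soft_power(corr, powers=[2, 6])
        for beta in (2, 6):
            k = soft_adjacency(corr, beta).sum(1)
            assert fits[beta] == pytest.approx(_scale_free_fit(k))


class TestTOM:
    def test_identical_rows_with_unit_link(self):
        # fully shared (binary) neighborhoods and a_01 = 1 give omega = 1
        a = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        tom = compute_tom(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency(self):
        tom = compute_tom(np.zeros((4, 4)))
        assert np.allclose(tom - np.eye(4), 0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = compute_tom(a)
        k = a.sum(1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(6) if u not in (i, j))
                expect = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_bounded_unit_diagonal(self, planted):
        _, lib = planted
        tom = compute_tom(soft_adjacency(gene_correlation(lib), 6))
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1)


class TestCutModules:
    def _block_tom(self, sizes, within=0.8, between=0.05, seed=0):
        n = sum(sizes)
        rng = np.random.default_rng(seed)
        tom = np.full((n, n), between) + 0.01 * rng.uniform(size=(n, n))
        tom = (tom + tom.T) / 2
        start = 0
        for s in sizes:
            tom[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(tom, 1.0)
        return np.clip(tom, 0, 1)

    def test_block_diagonal_recovered(self):
        sizes = [40, 35, 30]
        tom = self._block_tom(sizes)
        assign = cut_modules(tom, min_size=30)
        truth = np.repeat([1, 2, 3], sizes)
        assert adjusted_rand_score(truth, assign) == 1.0

    def test_small_satellite_block_unassigned(self):
        tom = self._block_tom([40, 10])
        assign = cut_modules(tom, min_size=30)
        assert np.all(assign[40:] == 0)
        assert np.all(assign[:40] == assign[0]) and assign[0] > 0

    def test_uniform_tom_deterministic(self):
        tom = np.full((50, 50), 0.5)
        np.fill_diagonal(tom, 1.0)
        a1 = cut_modules(tom, min_size=30)
        a2 = cut_modules(tom, min_size=30)
        assert np.array_equal(a1, a2)
        assert len(set(a1.tolist())) == 1  # one module or all unassigned


class TestEigenmapsAndKME:
    def test_identical_gene_module_reproduces_map(self, ico3):
        from cortexdem.synth import grf_maps

        base = grf_maps(ico3, 1, 20.0, np.random.default_rng(3))[0]
        Z = np.tile(base, (5, 1))
        lib = _library(ico3, Z)
        eig = cd.module_eigenmaps(lib, np.ones(5, dtype=int))
        mask = ico3.cortex_mask
        r = np.corrcoef(eig[0][mask], base[mask])[0, 1]
        assert r > 1 - 1e-9

    def test_kme_matches_direct_correlation(self, ico3):
        from cortexdem.synth import grf_maps

        rng = np.random.default_rng(4)
        Z = grf_maps(ico3, 8, 20.0, rng)
        lib = _library(ico3, Z)
        eig = cd.module_eigenmaps(lib, np.r_[np.ones(4, int), 2 * np.ones(4, int)])
        kme = cd.compute_kme(lib, eig)
        mask = ico3.cortex_mask
        for g in range(8):
            for m in range(2):
                assert kme[g, m] == pytest.approx(
                    np.corrcoef(Z[g][mask], eig[m][mask])[0, 1], abs=1e-12
                )
        # sign contract and antisymmetry
        neg = _library(ico3, -Z[:1])
        assert cd.compute_kme(neg, eig[:1])[0, 0] == pytest.approx(
            -kme[0, 0], abs=1e-12
        )


class TestFullPipeline:
    def test_planted_modules_recovered(self, planted):
        truth, lib = planted
        ms = cd.detect_modules(lib, min_size=30)
        assert adjusted_rand_score(truth.module_of_gene, ms.assignment) >= 0.9
        mask = lib.surface.cortex_mask
        for m in range(truth.eigenpatterns.shape[0]):
            rs = [
                abs(np.corrcoef(truth.eigenpatterns[m][mask], e[mask])[0, 1])
                for e in ms.eigenmaps
            ]
            assert max(rs) >= 0.9
        # membership contract: members load on their own module most strongly
        for mid in ms.module_ids:
            members = ms.assignment == mid
            own = np.median(ms.kme[members, mid - 1])
            others = [
                np.median(ms.kme[members, o - 1]) for o in ms.module_ids if o != mid
            ]
            assert own > max(others)
        # unassigned noise genes have kME centered on zero
        noise = (truth.module_of_gene == 0) & (ms.assignment == 0)
        assert abs(np.median(ms.kme[noise])) < 0.05

    def test_merge_collapses_duplicated_eigenpattern(self, ico3):
        truth = cd.make_truth(ico3, 1, 80, 0, 0, loading=0.9, seed=5)
        # two "modules" built on the same eigenpattern must merge to one
        lib = _library(ico3, truth.expr_truth)
        assignment = np.r_[np.ones(40, int), 2 * np.ones(40, int)]
        eig = cd.module_eigenmaps(lib, assignment)
        ms = cd.ModuleSet(
            gene_ids=list(lib.gene_ids), assignment=assignment, eigenmaps=eig,
            kme=cd.compute_kme(lib, eig),
        )
        merged = cd.merge_similar(ms, lib, threshold=0.9)
        assert len(merged.module_ids) == 1
        again = cd.merge_similar(merged, lib, threshold=0.9)
        assert np.array_equal(again.assignment, merged.assignment)

    def test_orthogonal_modules_not_merged(self, planted):
        truth, lib = planted
        ms = cd.detect_modules(lib, min_size=30)
        n_before = len(ms.module_ids)
        again = cd.merge_similar(ms, lib, threshold=0.9)
        assert len(again.module_ids) == n_before


class TestDropNoncortical:
    def test_flagged_module_removed(self, ico3):
        truth = cd.make_truth(ico3, 2, 50, 0, 0, loading=0.9, seed=6)
        lib = _library(ico3, truth.expr_truth, list(truth.gene_ids))
        ms = cd.detect_modules(lib, min_size=30)
        assert len(ms.module_ids) == 2
        # flag 80% of module 1's genes as non-cortical, 20% elsewhere
        rng = np.random.default_rng(0)
        m1 = ms.genes_in(1)
        rest = [g for g in lib.gene_ids if g not in m1]
        nc = list(rng.choice(m1, int(0.8 * len(m1)), replace=False)) + list(
            rng.choice(rest, int(0.2 * len(rest)), replace=False)
        )
        dropped = cd.drop_noncortical(ms, lib, nc)
        assert len(dropped.module_ids) == 1

    def test_no_flags_removes_nothing(self, planted):
        truth, lib = planted
        ms = cd.detect_modules(lib, min_size=30)
        kept = cd.drop_noncortical(ms, lib, [])
        assert np.array_equal(kept.assignment, ms.assignment)

    def test_alpha_zero_removes_nothing(self, planted):
        truth, lib = planted
        ms = cd.detect_modules(lib, min_size=30)
        kept = cd.drop_noncortical(ms, lib, list(lib.gene_ids[:50]), alpha=0.0)
        assert np.array_equal(kept.assignment, ms.assignment)
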