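"""Transcriptional distinctiveness, expression PCs, and localization tests."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import cortexdem as cd
from cortexdem.dem import DEMLibrary
from cortexdem.distinct import fit_distance_curve
from cortexdem.synth import grf_maps


def _library(surface, Z):
    return DEMLibrary(
        gene_ids=[f"g{i}" for i in range(Z.shape[0])], z=Z, surface=surface
    )


class TestTDMap:
    def test_zero_library(self, ico3):
        assert np.allclose(cd.td_map(_library(ico3, np.zeros((4, ico3.n_vertices)))), 0)

    def test_unit_abs_gene(self, ico3):
        Z = np.ones((1, ico3.n_vertices))
        Z[0, ::2] = -1
        assert np.allclose(cd.td_map(_library(ico3, Z)), 1.0)

    def test_invariant_to_gene_order_and_sign(self, ico3):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((6, ico3.n_vertices))
        td = cd.td_map(_library(ico3, Z))
        perm = rng.permutation(6)
        flipped = Z[perm].copy()
        flipped[0] *= -1
        assert np.allclose(td, cd.td_map(_library(ico3, flipped)))

    def test_iid_normal_analytic_limit(self, ico3):
        Z = np.random.default_rng(1).standard_normal((2000, ico3.n_vertices))
        td = cd.td_map(_library(ico3, Z))
        assert np.abs(td - np.sqrt(2 / np.pi)).max() < 0.05  # per-vertex
        assert abs(td.mean() - np.sqrt(2 / np.pi)) < 0.005


class TestTDPeaks:
    def test_pure_noise_rarely_suprathreshold(self, ico3, ens3_100):
        hits = 0
        rng = np.random.default_rng(2)
        for r in range(40):
            Z = grf_maps(ico3, 40, 20.0, rng)
            res = cd.find_td_peaks(_library(ico3, Z), ens3_100, n_perm=100, seed=r)
            hits += res.k > 0
        assert hits <= 8  # ~5% nominal; generous binomial slack at 40 runs

    def test_two_planted_patches_recovered(self, ico3, ens3_100):
        rng = np.random.default_rng(5)
        Z = grf_maps(ico3, 60, 20.0, rng)
        c2 = int(np.argmin(ico3.sphere @ ico3.sphere[0]))
        p1 = cd.geodesic_distance(ico3, [0]) < 35
        p2 = cd.geodesic_distance(ico3, [c2]) < 35
        Z[:, p1] += rng.choice([-5.0, 5.0], 60)[:, None]
        Z[:, p2] += rng.choice([-5.0, 5.0], 60)[:, None]
        res = cd.find_td_peaks(_library(ico3, Z), ens3_100, n_perm=100, seed=0)
        assert res.k == 2
        truth = np.zeros(ico3.n_vertices)
        truth[p1], truth[p2] = 1, 2
        supra = res.peak_label > 0
        assert adjusted_rand_score(truth[supra], res.peak_label[supra]) == 1.0

    def test_labels_partition_suprathreshold_set(self, ico3, ens3_100):
        # duplicated signatures across patches: k is not forced to 2, but the
        # labels must still partition exactly the suprathreshold vertices
        rng = np.random.default_rng(6)
        Z = grf_maps(ico3, 40, 20.0, rng)
        sig = rng.choice([-5.0, 5.0], 40)
        c2 = int(np.argmin(ico3.sphere @ ico3.sphere[0]))
        for c in (0, c2):
            Z[:, cd.geodesic_distance(ico3, [c]) < 30] += sig[:, None]
        res = cd.find_td_peaks(_library(ico3, Z), ens3_100, n_perm=100, seed=0)
        supra = res.td > res.threshold
        assert np.array_equal(res.peak_label > 0, supra & ico3.cortex_mask)


class TestTDGeneSets:
    def test_hand_computed_threshold(self, ico3, ens3_100):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((20, ico3.n_vertices))
        res = cd.TDResult(
            td=cd.td_map(_library(ico3, Z)), threshold=0.0,
            peak_label=np.zeros(ico3.n_vertices, dtype=int), k=1,
        )
        res.peak_label[5] = 1
        sets = cd.td_gene_sets(_library(ico3, Z), res)
        v = sets[1]["vertex"]
        z = Z[:, v]
        t = np.percentile(np.abs(z), 95)
        assert sets[1]["threshold"] == pytest.approx(t)
        assert sets[1]["high"] == [f"g{i}" for i in np.flatnonzero(z > t)]
        assert sets[1]["low"] == [f"g{i}" for i in np.flatnonzero(z < -t)]

    def test_nonnegative_z_gives_empty_low_list(self, ico3):
        Z = np.abs(np.random.default_rng(8).standard_normal((30, ico3.n_vertices)))
        res = cd.TDResult(
            td=cd.td_map(_library(ico3, Z)), threshold=0.0,
            peak_label=np.zeros(ico3.n_vertices, dtype=int), k=1,
        )
        res.peak_label[0] = 1
        sets = cd.td_gene_sets(_library(ico3, Z), res)
        assert sets[1]["low"] == []

    def test_symmetric_z_gives_roughly_balanced_lists(self, ico3):
        rng = np.random.default_rng(9)
        Z = rng.standard_normal((4000, ico3.n_vertices))
        res = cd.TDResult(
            td=cd.td_map(_library(ico3, Z)), threshold=0.0,
            peak_label=np.zeros(ico3.n_vertices, dtype=int), k=1,
        )
        res.peak_label[11] = 1
        sets = cd.td_gene_sets(_library(ico3, Z), res)
        hi, lo = len(sets[1]["high"]), len(sets[1]["low"])
        assert abs(hi - lo) < 0.4 * (hi + lo)


class TestLabelPeaks:
    def _result(self, ico3, verts):
        labels = np.zeros(ico3.n_vertices, dtype=int)
        labels[verts] = 1
        return cd.TDResult(
            td=np.ones(ico3.n_vertices), threshold=0.0, peak_label=labels, k=1
        )

    def test_peak_inside_one_parcel(self, ico3):
        parc = np.ones(ico3.n_vertices, dtype=int)
        parc[:100] = 2
        res = self._result(ico3, np.arange(10))
        assert cd.label_peaks(res, parc, {2: "apex"}) == {1: "apex"}

    def test_majority_parcel_wins(self, ico3):
        parc = np.ones(ico3.n_vertices, dtype=int)
        parc[:6] = 2
        res = self._result(ico3, np.arange(10))  # 6 in parcel 2, 4 in parcel 1
        assert cd.label_peaks(res, parc, {1: "a", 2: "b"}) == {1: "b"}

    def test_tie_goes_to_lower_parcel_id(self, ico3):
        parc = np.ones(ico3.n_vertices, dtype=int)
        parc[:5] = 2
        res = self._result(ico3, np.arange(10))  # 5 vs 5
        assert cd.label_peaks(res, parc, {1: "a", 2: "b"}) == {1: "a"}


class TestExpressionPCs:
    def test_rank_one_library(self, ico3, ens3_100):
        base = grf_maps(ico3, 1, 20.0, np.random.default_rng(3))[0]
        Z = np.outer(np.linspace(1, 2, 30), base)
        res = cd.expression_pcs(_library(ico3, Z), ens3_100, 3, n_perm=5)
        assert res["pct_variance"][0] > 99.0

    def test_pc_maps_orthogonal_and_variance_ordered(self, ico3, ens3_100):
        Z = grf_maps(ico3, 50, 20.0, np.random.default_rng(4))
        res = cd.expression_pcs(_library(ico3, Z), ens3_100, 4, n_perm=5)
        m = res["maps"][:, ico3.cortex_mask]
        gram = m @ m.T
        assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-6
        pv = res["pct_variance"]
        assert np.all(np.diff(pv) <= 1e-9) and pv.sum() <= 100 + 1e-9

    def test_noise_library_within_null_envelope(self, ico3, ens3_100):
        rng = np.random.default_rng(5)
        Z = grf_maps(ico3, 60, 20.0, rng)
        res = cd.expression_pcs(_library(ico3, Z), ens3_100, 3, n_perm=40, seed=1)
        assert (res["pct_variance"] <= res["null_pct_threshold"] * 1.15).all()


class TestDistanceDecoupling:
    def test_exact_function_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 400)
        y = 0.01 * x**2 + 2 * x + 5
        resid = y - fit_distance_curve(x, y)
        assert np.abs(resid).max() < 1e-4  # GCV spline on noise-free truth
        # polynomial fallback path (too few distinct distances) is exact
        xs = np.repeat(np.linspace(0, 100, 8), 10)
        ys = 0.001 * xs**3 - 0.02 * xs**2 + xs + 1
        assert np.abs(ys - fit_distance_curve(xs, ys)).max() < 1e-6

    def test_alien_parcel_has_max_residual(self, ico3):
        rng = np.random.default_rng(1)
        parc = cd.make_parcellation(ico3, 30, seed=2)
        Z = grf_maps(ico3, 40, 40.0, rng) * 0.05  # weak background
        alien = 7
        Z[:, parc == alien] += rng.choice([-3.0, 3.0], 40)[:, None]
        dd = cd.distance_decoupling(_library(ico3, Z), parc)
        rm = dd["residual_map"]
        centroids = dd["centroids"]
        assert np.nanargmax(rm) == centroids[alien]

    def test_residuals_sum_to_zero(self, ico3):
        rng = np.random.default_rng(2)
        parc = cd.make_parcellation(ico3, 25, seed=3)
        Z = grf_maps(ico3, 30, 20.0, rng)
        dd = cd.distance_decoupling(_library(ico3, Z), parc)
        assert abs(dd["residuals"].mean()) < 0.05 * dd["txd"].std()


class TestFetalLocalization:
    def _data(self, rng, n_regions=10, per_region=6, G=50):
        labels = np.repeat([f"r{i}" for i in range(n_regions)], per_region)
        expr = rng.standard_normal((G, len(labels)))
        genes = [f"g{i}" for i in range(G)]
        return expr, genes, labels

    def test_perfectly_localized_set_minimal_p(self):
        rng = np.random.default_rng(0)
        expr, genes, labels = self._data(rng)
        expr[:10, labels == "r3"] += 10.0
        obs, p = cd.fetal_localization_test(
            expr, genes, labels, ["r3"], genes[:10], n_perm=500, seed=1
        )
        assert p == pytest.approx(1 / 501)
        assert obs < 0.1

    def test_all_samples_targeted_is_degenerate(self):
        rng = np.random.default_rng(1)
        expr, genes, labels = self._data(rng)
        obs, p = cd.fetal_localization_test(
            expr, genes, labels, [f"r{i}" for i in range(10)], genes[:5],
            n_perm=100, seed=2,
        )
        assert obs == pytest.approx(0.5)
        assert p >= 0.5

    def test_random_sets_give_uniform_p(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        ps = []
        for r in range(200):
            # fresh data per repetition: uniformity is over datasets
            expr, genes, labels = self._data(rng, G=40)
            gs = list(rng.choice(genes, 10, replace=False))
            _, p = cd.fetal_localization_test(
                expr, genes, labels, ["r0"], gs, n_perm=200, seed=r
            )
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01
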