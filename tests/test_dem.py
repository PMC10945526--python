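"""Building dense expression maps from sparse donor samples."""

import numpy as np
import pytest

import cortexdem as cd
from cortexdem.dem import (
    DonorExpression,
    _rowwise_pearson,
    disjoint_subset_pairs,
    map_samples,
    nn_interpolate,
)


def _donor(coords, expr, genes=None, donor_id="d1", sex="M"):
    G = expr.shape[0]
    return DonorExpression(
        donor_id=donor_id,
        sex=sex,
        sample_coords=coords,
        expr=expr,
        gene_ids=genes or [f"g{i}" for i in range(G)],
    )


class TestMapSamples:
    def test_sample_at_vertex_assigned_there(self, ico3):
        d = _donor(ico3.vertices[[7, 100]], np.zeros((1, 2)))
        idx, keep = map_samples(d, ico3)
        assert keep.all() and list(idx) == [7, 100]

    def test_distant_sample_excluded(self, ico3):
        far = np.array([[0.0, 0.0, 300.0]])  # 200 mm above the pole
        d = _donor(np.vstack([ico3.vertices[0], far]), np.zeros((1, 2)))
        idx, keep = map_samples(d, ico3, max_dist_mm=20.0)
        assert keep.tolist() == [True, False]

    def test_matches_exhaustive_nearest_vertex(self, ico3):
        rng = np.random.default_rng(0)
        pts = ico3.vertices[rng.choice(ico3.n_vertices, 40, replace=False)]
        pts = pts + rng.uniform(-5, 5, pts.shape)
        d = _donor(pts, np.zeros((2, 40)))
        idx, keep = map_samples(d, ico3)
        brute = np.argmin(
            ((pts[:, None, :] - ico3.vertices[None]) ** 2).sum(-1), axis=1
        )
        assert np.array_equal(idx, brute)

    def test_all_excluded_is_error(self, ico3):
        d = _donor(np.array([[0.0, 0.0, 500.0]]), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            map_samples(d, ico3, max_dist_mm=20.0)


class TestNNInterpolate:
    def test_single_sample_gives_constant(self, ico3):
        out = nn_interpolate(np.array([12]), np.array([3.5]), ico3)
        assert np.allclose(out, 3.5)

    def test_full_sampling_is_identity(self, ico3):
        vals = np.random.default_rng(0).standard_normal(ico3.n_vertices)
        out = nn_interpolate(np.arange(ico3.n_vertices), vals, ico3)
        assert np.array_equal(out, vals)

    def test_matches_great_circle_brute_force(self, ico3):
        rng = np.random.default_rng(1)
        sv = np.sort(rng.choice(ico3.n_vertices, 50, replace=False))
        vals = rng.standard_normal(50)
        out = nn_interpolate(sv, vals, ico3)
        arc = np.arccos(np.clip(ico3.sphere @ ico3.sphere[sv].T, -1, 1))
        assert np.array_equal(out, vals[np.argmin(arc, axis=1)])


class TestBuildDems:
    def test_single_donor_rows_are_zscored(self, ico3):
        tr = cd.make_truth(ico3, 1, 8, 0, 0, seed=1)
        donors = cd.sample_donors(tr, 1, 100, 0.1, 0, 0, seed=2)
        lib = cd.build_dems(donors, ico3, 20.0)
        z = lib.z[:, ico3.cortex_mask]
        assert np.abs(z.mean(1)).max() < 1e-6
        assert np.abs(z.std(1) - 1).max() < 1e-6

    def test_duplicate_donor_averaging_idempotent(self, ico3):
        tr = cd.make_truth(ico3, 1, 6, 0, 0, seed=1)
        (d,) = cd.sample_donors(tr, 1, 80, 0.1, 0, 0, seed=3)
        twin = DonorExpression("d2", d.sex, d.sample_coords, d.expr, list(d.gene_ids))
        one = cd.build_dems([d], ico3, 20.0)
        two = cd.build_dems([d, twin], ico3, 20.0)
        assert np.allclose(one.z[:, ico3.cortex_mask], two.z[:, ico3.cortex_mask])

    def test_invariant_to_per_donor_affine_transforms(self, ico3):
        tr = cd.make_truth(ico3, 1, 6, 0, 0, seed=1)
        donors = cd.sample_donors(tr, 3, 80, 0.2, 0, 0, seed=4)
        shifted = [
            DonorExpression(d.donor_id, d.sex, d.sample_coords, 3.0 * d.expr - 7.0,
                            list(d.gene_ids))
            for d in donors
        ]
        a = cd.build_dems(donors, ico3, 20.0)
        b = cd.build_dems(shifted, ico3, 20.0)
        assert np.allclose(
            a.z[:, ico3.cortex_mask], b.z[:, ico3.cortex_mask], atol=1e-10
        )

    def test_noise_free_truth_recovery(self, ico3):
        tr = cd.make_truth(ico3, 3, 20, 0, 0, field_fwhm_mm=40.0, seed=2)
        donors = cd.sample_donors(tr, 6, 250, 0, 0, 0, seed=5)
        lib = cd.build_dems(donors, ico3, 20.0)
        r = _rowwise_pearson(
            lib.z[:, ico3.cortex_mask], tr.expr_truth[:, ico3.cortex_mask]
        )
        assert r.min() >= 0.95  # smoothing-limited ceiling

    def test_y_genes_use_male_donors_only(self, ico3):
        tr = cd.make_truth(ico3, 1, 4, 0, 0, seed=1)
        donors = cd.sample_donors(tr, 2, 100, 0, 0, 0, sex_labels=["M", "F"], seed=6)
        # corrupt the female donor's first gene: must not affect a Y gene
        donors[1].expr[0] = -donors[1].expr[0]
        chrom = {donors[0].gene_ids[0]: "Y"}
        lib = cd.build_dems(donors, ico3, 20.0, gene_chromosome=chrom)
        male_only = cd.build_dems([donors[0]], ico3, 20.0)
        assert np.allclose(
            lib.z[0, ico3.cortex_mask], male_only.z[0, ico3.cortex_mask]
        )
        assert lib.n_donors_per_gene[0] == 1
        assert lib.n_donors_per_gene[1] == 2

    def test_zero_variance_gene_skips_donor(self, ico3):
        tr = cd.make_truth(ico3, 1, 3, 0, 0, seed=1)
        donors = cd.sample_donors(tr, 2, 60, 0.1, 0, 0, seed=7)
        donors[0].expr[1, :] = 5.0  # flat gene in donor 1
        lib = cd.build_dems(donors, ico3, 20.0)
        assert lib.n_donors_per_gene[1] == 1
        assert np.isfinite(lib.z[1, ico3.cortex_mask]).all()


class TestSamplingStats:
    def test_density_formula(self, ico3):
        tr = cd.make_truth(ico3, 1, 2, 0, 0, seed=1)
        (d,) = cd.sample_donors(tr, 1, 100, seed=8)
        st = cd.sampling_stats(d, ico3)
        area = ico3.vertex_area[ico3.cortex_mask].sum()
        assert np.isclose(st.rho, 100 / area)
        assert np.isclose(st.d_mm, 1 / np.sqrt(st.rho))

    def test_doubling_samples_shrinks_distance_sqrt2(self, ico3):
        tr = cd.make_truth(ico3, 1, 2, 0, 0, seed=1)
        d100 = cd.sample_donors(tr, 1, 100, seed=8)[0]
        d200 = cd.sample_donors(tr, 1, 200, seed=8)[0]
        s1, s2 = cd.sampling_stats(d100, ico3), cd.sampling_stats(d200, ico3)
        assert np.isclose(s1.d_mm / s2.d_mm, np.sqrt(2))

    def test_density_distance_round_trip_at_study_scale(self):
        # 1 sample per (17.7 mm)^2 implies d = 17.7 mm by the same identity
        rho = 1.0 / 17.7**2
        assert np.isclose(1 / np.sqrt(rho), 17.7)


class TestSplitReproducibility:
    def test_triplet_split_enumeration(self):
        pairs = disjoint_subset_pairs(6, 3)
        assert len(pairs) == 10
        assert all(set(a).isdisjoint(b) for a, b in pairs)

    def test_duplicated_groups_reproduce_perfectly(self, ico3):
        tr = cd.make_truth(ico3, 1, 6, 0, 0, seed=1)
        (d,) = cd.sample_donors(tr, 1, 80, 0.1, 0, 0, seed=9)
        donors = [
            DonorExpression(f"d{i}", "M", d.sample_coords, d.expr, list(d.gene_ids))
            for i in range(4)
        ]
        rep = cd.split_reproducibility(donors, ico3, subset_size=2)
        assert np.allclose(rep["gene_r"], 1.0)

    def test_module_genes_beat_noise_genes(self, ico3):
        tr = cd.make_truth(ico3, 2, 20, 0, 40, field_fwhm_mm=40.0, seed=2)
        donors = cd.sample_donors(tr, 4, 200, 0.3, 0.1, 0.5, seed=10)
        rep = cd.split_reproducibility(donors, ico3, subset_size=2)
        mod = tr.module_of_gene != 0
        assert np.nanmedian(rep["gene_r"][:, mod]) > np.nanmedian(
            rep["gene_r"][:, ~mod]
        )

    def test_subset_size_guard(self, ico3):
        tr = cd.make_truth(ico3, 1, 3, 0, 0, seed=1)
        donors = cd.sample_donors(tr, 4, 50, seed=11)
        with pytest.raises(ValueError):
            cd.split_reproducibility(donors, ico3, subset_size=3)


class TestLearningCurve:
    def test_exact_recovery_noise_free(self):
        n = np.array([1.0, 2, 3, 4, 6])
        r = 0.8 - 0.5 * n**-1.0
        a, b, c, pred, conv = cd.fit_learning_curve(n, r, 10)
        assert conv and abs(a - 0.8) < 1e-6

    def test_constant_series(self):
        a, _, _, pred, _ = cd.fit_learning_curve([1, 2, 3], [0.6, 0.6, 0.6], 6)
        assert abs(a - 0.6) < 1e-3 and abs(pred - 0.6) < 1e-3

    def test_needs_three_sizes(self):
        with pytest.raises(ValueError):
            cd.fit_learning_curve([1, 2], [0.1, 0.2], 6)
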