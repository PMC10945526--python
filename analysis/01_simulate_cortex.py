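"""Simulate the study's inputs: a cortex-like mesh, planted expression truth,
six sparsely sampled donors, folding maps, and a parcellation.

The generated dataset mirrors the structure of a multi-donor cortical
microarray study: 6 donors x 250 samples on one hemisphere-like surface,
smooth co-expression structure (5 modules, loading 0.8), two focal
distinctive regions (modules with patch-like eigenpatterns), 30 genes with
a sharp shared expression border, and 120 genes without cortical
patterning.

Writes results/dataset/ for the downstream scripts.
"""

import cortexdem as cd
from cortexdem.dataset import write_dataset

SEED = 20240901

surface = cd.build_icosphere(4, 100.0)
truth = cd.make_truth(
    surface,
    n_modules=5,
    genes_per_module=60,
    n_boundary_genes=30,
    n_noise_genes=120,
    field_fwhm_mm=40.0,
    loading=0.8,
    n_focal_modules=2,
    seed=SEED,
)
donors = cd.sample_donors(
    truth, n_donors=6, samples_per_donor=250, sample_noise_sd=0.3,
    donor_scale_sd=0.1, donor_shift_sd=0.5, seed=SEED + 1,
)
folds = cd.make_folds(surface, n_waves=1, amplitude=2.0, seed=SEED + 2)
parcellation = cd.make_parcellation(surface, 50, seed=SEED + 3)

write_dataset("results/dataset", surface, donors, truth, folds, parcellation)

n_genes = truth.n_genes
print(f"mesh: {surface.n_vertices} vertices, {surface.total_area:.0f} mm^2")
print(f"genes: {n_genes} ({(truth.module_of_gene > 0).sum()} module, "
      f"{(truth.module_of_gene == -1).sum()} border, "
      f"{(truth.module_of_gene == 0).sum()} noise)")
print(f"donors: {len(donors)} x {donors[0].expr.shape[1]} samples")
print("wrote results/dataset/")
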