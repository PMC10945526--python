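"""Quantify DEM reproducibility between disjoint donor subsets and
extrapolate with a learning curve.

Six donors admit exactly 10 disjoint triplet pairings; gene-level
reproducibility is the cross-vertex correlation per gene between
sub-libraries, vertex-level reproducibility the cross-gene rank correlation
per vertex. A saturating learning curve r(n) = a - b n^-c extrapolates the
full-cohort reproducibility.

Reads results/dataset/; writes results/reproducibility/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import cortexdem as cd
from cortexdem.dataset import read_dataset

ds = read_dataset("results/dataset")
surface, donors = ds["surface"], ds["donors"]
structured = ds["module_of_gene"] != 0

out = Path("results/reproducibility")
out.mkdir(parents=True, exist_ok=True)

rows, means = [], []
for size in (1, 2, 3):
    rep = cd.split_reproducibility(donors, surface, subset_size=size)
    gr = rep["gene_r"]
    means.append(float(np.nanmean(gr[:, structured])))
    rows.append(
        {
            "subset_size": size,
            "n_splits": len(rep["splits"]),
            "gene_r_structured_median": float(np.nanmedian(gr[:, structured])),
            "gene_r_noise_median": float(np.nanmedian(gr[:, ~structured])),
            "vertex_r_median": float(np.nanmedian(rep["vertex_r"])),
        }
    )
    if size == 3:
        pd.DataFrame(
            {"gene": donors[0].gene_ids, "median_split_r": np.nanmedian(gr, axis=0)}
        ).to_csv(out / "gene_reproducibility.csv", index=False)

table = pd.DataFrame(rows)
a, b, c, pred6, converged = cd.fit_learning_curve([1, 2, 3], means, 6)
table.to_csv(out / "split_summary.csv", index=False)
pd.DataFrame(
    [{"a": a, "b": b, "c": c, "predicted_r_at_6": pred6, "converged": converged}]
).to_csv(out / "learning_curve.csv", index=False)

print(table.to_string(index=False))
print(f"\nlearning curve: r(n) = {a:.3f} - {b:.3f} n^-{c:.2f}; "
      f"predicted full-cohort (n=6) gene-level r = {pred6:.3f}")
print("noise genes reproduce at r ~ 0: their maps carry no donor-shared signal")
print("wrote results/reproducibility/")
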