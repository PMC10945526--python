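"""On-disk layout for a synthetic study: surfaces, donors, truth, gene sets.

A dataset directory contains ``mesh.surf.gii`` and ``sphere.surf.gii``, one
``<donor>.expr.tsv`` (genes x samples) per donor plus a shared
``samples.csv`` (sample_id, x, y, z, donor, sex), the planted truth as
``truth.tsv``, marker gene sets as ``markers.gmt``, fold maps as CSV, and a
``parcellation.csv`` label map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .dem import DonorExpression
from .surface import CorticalSurface, ScalarMap

__all__ = ["write_dataset", "read_dataset"]


def write_dataset(
    outdir,
    surface: CorticalSurface,
    donors: list,
    truth=None,
    folds=None,
    parcellation=None,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_surface_gifti(surface, out / "mesh.surf.gii")
    io.write_surface_gifti(surface, out / "sphere.surf.gii", sphere=True)

    rows = []
    for d in donors:
        pd.DataFrame(
            d.expr,
            index=pd.Index(d.gene_ids, name="gene"),
            columns=[f"{d.donor_id}_s{i}" for i in range(d.expr.shape[1])],
        ).to_csv(out / f"{d.donor_id}.expr.tsv", sep="\t")
        for i, (x, y, z) in enumerate(d.sample_coords):
            rows.append(
                {"sample_id": f"{d.donor_id}_s{i}", "x": x, "y": y, "z": z,
                 "donor": d.donor_id, "sex": d.sex}
            )
    pd.DataFrame(rows).to_csv(out / "samples.csv", index=False)

    if truth is not None:
        pd.DataFrame(
            truth.expr_truth, index=pd.Index(truth.gene_ids, name="gene")
        ).to_csv(out / "truth.tsv", sep="\t")
        io.write_gmt(truth.marker_sets, out / "markers.gmt")
        meta = {
            "seed": truth.seed,
            "module_of_gene": np.asarray(truth.module_of_gene).tolist(),
            "boundary_genes": [
                {"gene": g, "axis": list(map(float, a)), "offset": float(o),
                 "width": float(w)}
                for g, a, o, w in truth.boundary_genes
            ],
        }
        (out / "truth.json").write_text(json.dumps(meta))
    if folds is not None:
        sulc, curv, _ = folds
        io.write_map_csv(ScalarMap(sulc, surface, "sulcal_depth"), out / "sulc.csv")
        io.write_map_csv(ScalarMap(curv, surface, "curvature"), out / "curv.csv")
    if parcellation is not None:
        io.write_map_csv(
            ScalarMap(parcellation.astype(float), surface, "parcel"),
            out / "parcellation.csv",
        )


def read_dataset(indir) -> dict:
    """Load a dataset directory back into in-memory objects."""
    d = Path(indir)
    surface = io.read_surface_gifti(d / "mesh.surf.gii", d / "sphere.surf.gii")
    samples = pd.read_csv(d / "samples.csv")
    donors = []
    for donor_id, group in samples.groupby("donor", sort=False):
        expr = pd.read_csv(d / f"{donor_id}.expr.tsv", sep="\t", index_col=0)
        expr = expr[group["sample_id"]]
        donors.append(
            DonorExpression(
                donor_id=str(donor_id),
                sex=str(group["sex"].iloc[0]),
                sample_coords=group[["x", "y", "z"]].to_numpy(float),
                expr=expr.to_numpy(float),
                gene_ids=[str(g) for g in expr.index],
            )
        )
    out = {"surface": surface, "donors": donors}
    if (d / "truth.tsv").exists():
        tdf = pd.read_csv(d / "truth.tsv", sep="\t", index_col=0)
        out["truth_expr"] = tdf.to_numpy(float)
        out["truth_genes"] = [str(g) for g in tdf.index]
        out["markers"] = io.read_gmt(d / "markers.gmt")
        meta = json.loads((d / "truth.json").read_text())
        out["module_of_gene"] = np.asarray(meta["module_of_gene"])
        out["boundary_genes"] = meta["boundary_genes"]
    for name, f in [("sulc", "sulc.csv"), ("curv", "curv.csv")]:
        if (d / f).exists():
            out[name] = io.read_map_csv(d / f, surface).values
    if (d / "parcellation.csv").exists():
        out["parcellation"] = io.read_map_csv(
            d / "parcellation.csv", surface
        ).values.astype(int)
    return out
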