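"""Reading and writing surfaces, vertex maps, labels, and gene sets.

GIFTI handling goes through nibabel; OBJ through trimesh. CSV maps are one
value per vertex with a single header line naming the map. All vertex indices
are 0-based on disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .surface import CorticalSurface, ScalarMap

__all__ = [
    "write_surface_gifti",
    "read_surface_gifti",
    "write_surface_obj",
    "read_surface_obj",
    "write_map_gifti",
    "read_map_gifti",
    "write_map_csv",
    "read_map_csv",
    "write_label_gifti",
    "read_label_gifti",
    "read_gmt",
    "write_gmt",
]


def write_surface_gifti(surface: CorticalSurface, path, sphere: bool = False) -> None:
    """Write vertices+faces (or the spherical projection) as a .surf.gii."""
    import nibabel as nib

    coords = surface.sphere if sphere else surface.vertices
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                surface.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def read_surface_gifti(path, sphere_path=None) -> CorticalSurface:
    """Read a .surf.gii; if no sphere file is given, vertices are normalized."""
    import nibabel as nib

    img = nib.load(str(path))
    coords = faces = None
    for da in img.darrays:
        if da.intent == 1008:  # POINTSET
            coords = np.asarray(da.data, dtype=float)
        elif da.intent == 1009:  # TRIANGLE
            faces = np.asarray(da.data, dtype=np.int64)
    if coords is None or faces is None:
        raise ValueError(f"{path}: missing POINTSET or TRIANGLE array")
    if sphere_path is not None:
        simg = nib.load(str(sphere_path))
        sphere = np.asarray(
            next(d for d in simg.darrays if d.intent == 1008).data, dtype=float
        )
    else:
        sphere = coords.copy()
    sphere = sphere / np.linalg.norm(sphere, axis=1, keepdims=True)
    return CorticalSurface(coords, faces, sphere)


def write_surface_obj(surface: CorticalSurface, path) -> None:
    import trimesh

    trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    ).export(str(path))


def read_surface_obj(path) -> CorticalSurface:
    import trimesh

    m = trimesh.load_mesh(str(path), process=False)
    v = np.asarray(m.vertices, dtype=float)
    sphere = v / np.linalg.norm(v, axis=1, keepdims=True)
    return CorticalSurface(v, np.asarray(m.faces, dtype=np.int64), sphere)


def _check_length(values, surface):
    if surface is not None and len(values) != surface.n_vertices:
        raise ValueError(
            f"map has {len(values)} values but surface has {surface.n_vertices} vertices"
        )


def write_map_gifti(m: ScalarMap, path) -> None:
    import nibabel as nib

    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(m.values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
            )
        ]
    )
    img.meta["Name"] = m.name
    nib.save(img, str(path))


def read_map_gifti(path, surface: CorticalSurface = None) -> ScalarMap:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.darrays[0].data, dtype=float)
    _check_length(values, surface)
    return ScalarMap(values, surface, img.meta.get("Name", ""))


def write_map_csv(m: ScalarMap, path) -> None:
    pd.DataFrame({m.name or "value": m.values}).to_csv(path, index=False)


def read_map_csv(path, surface: CorticalSurface = None) -> ScalarMap:
    df = pd.read_csv(path)
    values = df.iloc[:, 0].to_numpy(dtype=float)
    _check_length(values, surface)
    return ScalarMap(values, surface, str(df.columns[0]))


def write_label_gifti(labels: np.ndarray, path, names: dict | None = None) -> None:
    import nibabel as nib

    labels = np.asarray(labels, dtype=np.int32)
    table = nib.gifti.GiftiLabelTable()
    for lab in np.unique(labels):
        gl = nib.gifti.GiftiLabel(key=int(lab))
        gl.label = (names or {}).get(int(lab), str(int(lab)))
        table.labels.append(gl)
    img = nib.gifti.GiftiImage(
        darrays=[nib.gifti.GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL")],
        labeltable=table,
    )
    nib.save(img, str(path))


def read_label_gifti(path, surface: CorticalSurface = None):
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.darrays[0].data, dtype=int)
    _check_length(labels, surface)
    names = {int(l.key): l.label for l in img.labeltable.labels}
    return labels, names


# ----------------------------------------------------------------- gene sets
def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, name<TAB>description<TAB>genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")
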