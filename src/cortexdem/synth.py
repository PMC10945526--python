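"""Synthetic cortical datasets with known ground truth.

Emulates the statistical structure of a sparse multi-donor cortical
microarray study on a hemisphere-like mesh: smooth spatial eigenpatterns with
planted co-expression modules, genes with sharp step-like expression borders
across great circles, pure-noise genes without cortical patterning, sparse
per-donor sampling with affine donor effects, sinusoidal folding fields with
known orientation, and roughly even-sized contiguous parcellations.

Eigenpatterns are Gaussian random fields (smoothed, z-scored white noise)
rather than band-limited spherical harmonics so that their spatial
autocorrelation scale is controlled by the same FWHM knob as the map-building
smoothing step -- the property spin-test calibration is sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.cluster import KMeans

from .surface import CorticalSurface, TangentField, geodesic_distance, smooth_map

__all__ = [
    "GroundTruth",
    "make_truth",
    "sample_donors",
    "make_folds",
    "make_parcellation",
    "grf_maps",
]


def _zscore_rows(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu = x[..., mask].mean(axis=-1, keepdims=True)
    sd = x[..., mask].std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def grf_maps(
    surface: CorticalSurface, n_maps: int, fwhm_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary unit-variance Gaussian random fields on the surface.

    White vertex noise is smoothed with the geodesic Gaussian kernel and then
    divided by the per-vertex kernel norm, which equalizes the field variance
    across vertices. Without this correction the fields inherit mesh-locked
    variance structure (vertex areas and degrees vary), which would make
    rotation-based null models anticonservative for reasons unrelated to the
    signal being modeled. Rows are finally z-scored across unmasked vertices.
    """
    from .surface import smoothing_matrix

    noise = rng.standard_normal((n_maps, surface.n_vertices))
    if fwhm_mm > 0:
        W = smoothing_matrix(surface, fwhm_mm)
        fields = (W @ noise.T).T
        rownorm = np.sqrt(np.asarray(W.multiply(W).sum(axis=1)).ravel())
        rownorm[rownorm == 0] = 1.0
        fields = fields / rownorm
        fields[:, ~surface.cortex_mask] = np.nan
    else:
        fields = noise
    return _zscore_rows(np.where(np.isfinite(fields), fields, 0.0), surface.cortex_mask)


@dataclass
class GroundTruth:
    """Planted gene-level truth on a surface.

    ``module_of_gene`` is 0 for noise genes, -1 for border genes, and the
    1-based module id for module genes.
    """

    surface: CorticalSurface
    expr_truth: np.ndarray  # (G, V)
    gene_ids: list
    module_of_gene: np.ndarray  # (G,)
    eigenpatterns: np.ndarray  # (M, V)
    boundary_genes: list = field(default_factory=list)  # (gene, axis, offset, width)
    marker_sets: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def make_truth(
    surface: CorticalSurface,
    n_modules: int = 5,
    genes_per_module: int = 100,
    n_boundary_genes: int = 0,
    n_noise_genes: int = 100,
    field_fwhm_mm: float = 20.0,
    loading: float = 0.8,
    border_width_mm: tuple = (1.0, 3.0),
    border_noise_sd: float = 0.1,
    share_border: bool = True,
    n_focal_modules: int = 0,
    focal_radius_mm: float = 30.0,
    seed: int = 0,
) -> GroundTruth:
    """Plant module, border, and noise genes on a surface.

    Module gene = loading * eigenpattern + sqrt(1-loading^2) * independent GRF.
    Border gene = logistic step across a great circle plus small noise; with
    ``share_border`` (default) all border genes share one circle, emulating
    an areal boundary marked by many genes, with per-gene step widths.
    Noise gene = unsmoothed white noise (no spatial structure).

    ``n_focal_modules`` additionally plants modules whose eigenpattern is a
    smoothed focal patch (radius ``focal_radius_mm``) instead of a global
    random field: their member genes take extreme values inside one compact
    region, the planted analogue of a transcriptionally distinctive area.
    Focal modules have ``genes_per_module`` genes each and module ids
    following the smooth modules'.
    """
    if field_fwhm_mm <= 0:
        raise ValueError("field_fwhm_mm must be positive")
    if not (0 < loading <= 1):
        raise ValueError("loading must be in (0, 1]")
    G = (n_modules + n_focal_modules) * genes_per_module + n_boundary_genes + n_noise_genes
    if G < 1:
        raise ValueError("at least one gene is required")
    rng = np.random.default_rng(seed)
    V = surface.n_vertices
    mask = surface.cortex_mask
    radius = float(np.linalg.norm(surface.vertices, axis=1).mean())

    eig = grf_maps(surface, n_modules, field_fwhm_mm, rng) if n_modules else np.zeros((0, V))
    focal = []
    for _ in range(n_focal_modules):
        center = int(rng.choice(np.flatnonzero(mask)))
        patch = (geodesic_distance(surface, [center]) < focal_radius_mm).astype(float)
        f = smooth_map(patch, surface, field_fwhm_mm / 2.0)
        focal.append(_zscore_rows(np.where(np.isfinite(f), f, 0.0)[None], mask)[0])
    if focal:
        eig = np.vstack([eig, focal]) if eig.size else np.asarray(focal)

    rows, gene_ids, module_of = [], [], []
    marker_sets: dict[str, list] = {}
    for m in range(n_modules + n_focal_modules):
        resid = grf_maps(surface, genes_per_module, field_fwhm_mm, rng)
        g = loading * eig[m] + np.sqrt(1 - loading**2) * resid
        rows.append(_zscore_rows(g, mask))
        tag = f"M{m + 1}" if m < n_modules else f"F{m - n_modules + 1}"
        names = [f"{tag}_G{j}" for j in range(genes_per_module)]
        gene_ids += names
        module_of += [m + 1] * genes_per_module
        key = f"module_{m + 1}" if m < n_modules else f"focal_{m - n_modules + 1}"
        marker_sets[key] = names

    boundary_genes = []
    border_names = []
    if n_boundary_genes and share_border:
        shared_axis = rng.standard_normal(3)
        shared_axis /= np.linalg.norm(shared_axis)
        shared_offset = rng.uniform(-0.3, 0.3)
    for j in range(n_boundary_genes):
        if share_border:
            axis, offset = shared_axis, shared_offset
        else:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            offset = rng.uniform(-0.3, 0.3)
        width = rng.uniform(*border_width_mm)
        s = radius * (np.arcsin(np.clip(surface.sphere @ axis, -1, 1)) - np.arcsin(offset))
        g = expit(s / width) + border_noise_sd * rng.standard_normal(V)
        rows.append(_zscore_rows(g[None, :], mask))
        name = f"BORDER_G{j}"
        gene_ids.append(name)
        module_of.append(-1)
        boundary_genes.append((name, axis, offset, width))
        border_names.append(name)
    if border_names:
        marker_sets["border"] = border_names

    if n_noise_genes:
        g = rng.standard_normal((n_noise_genes, V))
        rows.append(_zscore_rows(g, mask))
        names = [f"NOISE_G{j}" for j in range(n_noise_genes)]
        gene_ids += names
        module_of += [0] * n_noise_genes
        marker_sets["noise"] = names

    expr = np.vstack([r if r.ndim == 2 else r[None] for r in rows])
    return GroundTruth(
        surface=surface,
        expr_truth=expr,
        gene_ids=gene_ids,
        module_of_gene=np.asarray(module_of),
        eigenpatterns=eig,
        boundary_genes=boundary_genes,
        marker_sets=marker_sets,
        seed=seed,
    )


def sample_donors(
    truth: GroundTruth,
    n_donors: int = 6,
    samples_per_donor: int = 200,
    sample_noise_sd: float = 0.3,
    donor_scale_sd: float = 0.1,
    donor_shift_sd: float = 0.5,
    jitter_mm: float = 0.0,
    sex_labels=None,
    resample_noise_genes: bool = True,
    seed: int = 0,
):
    """Sparse per-donor sampling of the planted truth with affine donor effects.

    Each donor draws sample vertices without replacement; the measured value
    is ``donor_scale * truth + donor_shift + N(0, sample_noise_sd)``.  Donor
    effects are affine because per-donor z-scoring in map building must remove
    exactly this nuisance class.

    Genes without cortical patterning (``module_of_gene == 0``) measure pure
    noise: with ``resample_noise_genes`` (default) their values are drawn
    fresh per donor rather than taken from the shared truth row, so no
    consistent spatial pattern survives donor averaging -- the defining
    feature of non-cortically-expressed genes. Disable to sample every gene
    from the stored truth verbatim.
    """
    from .dem import DonorExpression

    surface = truth.surface
    V = surface.n_vertices
    if samples_per_donor < 2:
        raise ValueError("samples_per_donor must be >= 2")
    unmasked = np.flatnonzero(surface.cortex_mask)
    if samples_per_donor > unmasked.size:
        raise ValueError("samples_per_donor exceeds available vertices")
    if sex_labels is None:
        sex_labels = ["M" if i % 2 == 0 else "F" for i in range(n_donors)]
    donors = []
    for i in range(n_donors):
        rng = np.random.default_rng((seed, i))
        verts = rng.choice(unmasked, size=samples_per_donor, replace=False)
        scale = 1.0 + donor_scale_sd * rng.standard_normal()
        shift = donor_shift_sd * rng.standard_normal()
        base = truth.expr_truth[:, verts].copy()
        if resample_noise_genes:
            is_noise = truth.module_of_gene == 0
            base[is_noise] = rng.standard_normal((is_noise.sum(), samples_per_donor))
        expr = (
            scale * base
            + shift
            + sample_noise_sd * rng.standard_normal((truth.n_genes, samples_per_donor))
        )
        coords = surface.vertices[verts].copy()
        if jitter_mm > 0:
            coords += rng.uniform(-jitter_mm, jitter_mm, coords.shape)
        donors.append(
            DonorExpression(
                donor_id=f"donor{i + 1}",
                sex=sex_labels[i],
                sample_coords=coords,
                expr=expr,
                gene_ids=list(truth.gene_ids),
            )
        )
    return donors


def make_folds(
    surface: CorticalSurface,
    n_waves: int = 1,
    amplitude: float = 1.0,
    wavelength_mm: float = 60.0,
    seed: int = 0,
):
    """Sinusoidal plane-wave folding fields with known orientation.

    Returns (sulc, curv, true_orientation): sulcal depth as a sum of plane
    waves, curvature as its graph Laplacian, and the analytic tangential
    orientation of the dominant (first) wave at each vertex.
    """
    rng = np.random.default_rng(seed)
    V = surface.n_vertices
    coords = surface.vertices
    sulc = np.zeros(V)
    qs = []
    for _ in range(max(n_waves, 0)):
        q = rng.standard_normal(3)
        q /= np.linalg.norm(q)
        q *= 2 * np.pi / wavelength_mm
        phase = rng.uniform(0, 2 * np.pi)
        sulc += amplitude * np.sin(coords @ q + phase)
        qs.append(q)

    # discrete (graph) Laplacian as a curvature-like second field
    adj = surface.adjacency(weighted=False)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    curv = sulc - (adj @ sulc) / deg

    tb = surface.tangent_basis()
    if amplitude == 0 or not qs:
        coeffs = np.zeros((V, 2))
    else:
        q0 = qs[0]
        # tangential component of the dominant wave vector at each vertex
        coeffs = np.column_stack([tb[:, 0] @ q0, tb[:, 1] @ q0])
    return sulc, curv, TangentField(coeffs, surface)


def make_parcellation(surface: CorticalSurface, n_parcels: int, seed: int = 0) -> np.ndarray:
    """Contiguous, roughly even-sized parcels from spherical k-means.

    Labels are 1..n_parcels on unmasked vertices and 0 outside the mask.
    Disconnected islands are reassigned to the neighboring parcel sharing the
    longest boundary until every parcel is connected on the mesh graph.
    """
    import scipy.sparse.csgraph as csgraph

    mask = surface.cortex_mask
    pts = surface.sphere[mask]
    if n_parcels < 1 or n_parcels > pts.shape[0]:
        raise ValueError("n_parcels out of range")
    km = KMeans(n_clusters=n_parcels, n_init=10, random_state=np.random.default_rng(seed).integers(2**31))
    sub = km.fit_predict(pts) + 1
    labels = np.zeros(surface.n_vertices, dtype=int)
    labels[mask] = sub

    adj = surface.adjacency(weighted=False)
    for _ in range(100):
        moved = False
        for lab in range(1, n_parcels + 1):
            nodes = np.flatnonzero(labels == lab)
            if nodes.size == 0:
                continue
            subadj = adj[np.ix_(nodes, nodes)]
            ncomp, comp = csgraph.connected_components(subadj, directed=False)
            if ncomp <= 1:
                continue
            sizes = np.bincount(comp)
            keep = np.argmax(sizes)
            for c in range(ncomp):
                if c == keep:
                    continue
                island = nodes[comp == c]
                # neighbor parcel with the most shared boundary edges
                nbr_counts: dict[int, int] = {}
                for v in island:
                    for u in adj[v].indices:
                        lu = labels[u]
                        if lu != lab and lu != 0:
                            nbr_counts[lu] = nbr_counts.get(lu, 0) + 1
                if nbr_counts:
                    target = max(sorted(nbr_counts), key=lambda k: nbr_counts[k])
                    labels[island] = target
                    moved = True
        if not moved:
            break
    return labels
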