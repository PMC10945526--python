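"""Per-gene expression-gradient fields and border-detection statistics.

Each gene's dense expression map has a tangential gradient at every vertex
(orientation and magnitude of local expression change). Averaging magnitudes
across genes gives a map of how fast the transcriptome is changing locally;
regions where that mean is higher than expected under independent per-gene
spins are candidate areal borders. The principal orientation at a vertex is
the leading axis of the gene gradient vectors' second-moment matrix --
uncentered, because the summary is axial, not directed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ttest_ind

from .dem import DEMLibrary
from .spin import SpinEnsemble, max_stat_threshold
from .surface import CorticalSurface, TangentField, gradient_operator

__all__ = [
    "GradientLibrary",
    "gene_gradients",
    "high_gradient_regions",
    "principal_orientation",
    "rank_border_genes",
    "ish_boundary",
]


@dataclass
class GradientLibrary:
    """Per-gene tangent gradient fields, (G, V, 2) in the tangent basis."""

    gene_ids: list
    coeffs: np.ndarray  # (G, V, 2)
    surface: CorticalSurface
    geometry: str = "folded"

    @property
    def magnitudes(self) -> np.ndarray:
        """(G, V) gradient magnitudes in map-units/mm."""
        return np.linalg.norm(self.coeffs, axis=2)

    @property
    def mean_magnitude(self) -> np.ndarray:
        return self.magnitudes.mean(axis=0)

    def field(self, g: int) -> TangentField:
        return TangentField(self.coeffs[g], self.surface, self.geometry)


def gene_gradients(
    library: DEMLibrary, geometry: str = "folded"
) -> GradientLibrary:
    """Tangential gradient of every gene map in a DEM library."""
    surface = library.surface
    Gx, Gy, degenerate = gradient_operator(surface, geometry)
    filled = np.where(np.isfinite(library.z), library.z, 0.0)
    coeffs = np.stack([(Gx @ filled.T).T, (Gy @ filled.T).T], axis=2)
    coeffs[:, degenerate, :] = 0.0
    return GradientLibrary(
        gene_ids=list(library.gene_ids), coeffs=coeffs, surface=surface, geometry=geometry
    )


def high_gradient_regions(
    gradlib: GradientLibrary,
    ensemble: SpinEnsemble,
    quantile: float = 0.95,
    n_perm: int | None = None,
    seed: int = 0,
):
    """Vertices whose mean gradient magnitude beats the spin max-statistic.

    Per permutation each gene's magnitude map is independently spun, the mean
    recomputed, and the map maximum recorded; the returned binary mask marks
    vertices above the chosen quantile of those maxima.
    """
    mags = gradlib.magnitudes
    thr, maxima = max_stat_threshold(
        mags, ensemble, n_perm=n_perm, quantile=quantile, seed=seed
    )
    mask = (gradlib.mean_magnitude > thr) & gradlib.surface.cortex_mask
    return mask, thr, maxima


def principal_orientation(gradlib: GradientLibrary):
    """Leading axis of gene gradient vectors at each vertex.

    Eigen-decomposition of the uncentered 2x2 second-moment matrix of the
    per-gene gradient 2-vectors. Returns ``(orientation_deg, pct_variance)``:
    axial angles in [0, 180) (NaN where all vectors vanish) and the leading
    eigenvalue's share of the total, in percent.
    """
    c = gradlib.coeffs  # (G, V, 2)
    sxx = (c[:, :, 0] ** 2).mean(0)
    syy = (c[:, :, 1] ** 2).mean(0)
    sxy = (c[:, :, 0] * c[:, :, 1]).mean(0)
    tr = sxx + syy
    # eigenvalues of [[sxx, sxy], [sxy, syy]]
    disc = np.sqrt(np.maximum((sxx - syy) ** 2 + 4 * sxy**2, 0.0))
    lam1 = 0.5 * (tr + disc)
    theta = 0.5 * np.degrees(np.arctan2(2 * sxy, sxx - syy)) % 180.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(tr > 0, 100.0 * lam1 / tr, np.nan)
    theta = np.where(tr > 0, theta, np.nan)
    return theta, pct


def rank_border_genes(
    gradlib: GradientLibrary,
    boundary_vertices,
    marker_sets: dict | None = None,
    n_null: int = 10000,
    seed: int = 0,
):
    """Rank genes by mean gradient magnitude over boundary vertices.

    Rank 1 is the sharpest border gene. For each marker set, significance is
    the fraction of size-matched random gene sets whose median rank is at
    least as low (plus-one corrected).

    Returns ``(table, set_pvalues)`` where ``table`` maps gene -> (mean
    gradient, rank).
    """
    boundary_vertices = np.asarray(boundary_vertices, dtype=int)
    if boundary_vertices.size == 0:
        raise ValueError("boundary vertex set is empty")
    mags = gradlib.magnitudes[:, boundary_vertices].mean(axis=1)
    order = np.argsort(-mags, kind="stable")
    ranks = np.empty(len(mags), dtype=int)
    ranks[order] = np.arange(1, len(mags) + 1)
    table = {g: (float(mags[i]), int(ranks[i])) for i, g in enumerate(gradlib.gene_ids)}

    pvals = {}
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(gradlib.gene_ids)}
    for name, genes in (marker_sets or {}).items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            pvals[name] = np.nan
            continue
        obs = np.median(ranks[idx])
        # size-matched gene sets drawn without replacement
        null = np.empty(n_null)
        for r in range(n_null):
            null[r] = np.median(ranks[rng.choice(len(ranks), size=len(idx), replace=False)])
        pvals[name] = float((1 + (null <= obs).sum()) / (1 + n_null))
    return table, pvals


def ish_boundary(profile, min_group: int = 2, equal_var: bool = True):
    """Locate a putative areal boundary in a 1-D staining-intensity profile.

    For each candidate split (at least ``min_group`` columns per side) a
    two-sample t statistic compares the column means to the right and left of
    the split; the split with the largest |t| (lowest index on ties) is the
    boundary. The pooled-variance statistic is the default: for a pure
    intensity ramp it peaks at the central split, whereas the Welch variant
    (``equal_var=False``) is flat across splits there and cannot localize.

    Returns ``(boundary_column, t_value)``; a constant profile raises.
    """
    x = np.asarray(profile, dtype=float).ravel()
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 columns")
    best_c, best_t = None, 0.0
    for c in range(min_group, n - min_group + 1):
        left, right = x[:c], x[c:]
        if left.std() == 0 and right.std() == 0:
            if left.mean() == right.mean():
                continue
            # perfect separation: infinite t, sign of the step
            t = np.inf if right.mean() > left.mean() else -np.inf
        else:
            t = ttest_ind(right, left, equal_var=equal_var).statistic
            if not np.isfinite(t):
                continue
        if best_c is None or abs(t) > abs(best_t) + 1e-12:
            best_c, best_t = c, float(t)
    if best_c is None:
        raise ValueError("degenerate profile: no split has variance")
    return best_c, best_t
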