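"""Spherical-rotation ("spin") null models and map-comparison statistics.

Cortical maps are spatially autocorrelated, so comparing two maps with a
naive permutation test inflates false positives. The spin test preserves each
map's autocorrelation by randomly rotating its spherical projection and
re-reading values from the nearest original vertices. All p-values use the
(1 + exceedances) / (1 + n_spins) convention, which keeps the test valid at
any finite number of spins.

Only pure rotations are used (single hemisphere, no mirroring), and spun
values are reassigned to the nearest vertex rather than interpolated
barycentrically; duplicated assignments are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata, skew, t as t_dist

from .surface import CorticalSurface, TangentField, asvalues

__all__ = [
    "SpinEnsemble",
    "make_spins",
    "spin_test",
    "max_stat_threshold",
    "spun_interpolated_null",
    "glm_cluster_correction",
    "parcel_spin_correlation",
    "spin_tangent_field",
]


@dataclass
class SpinEnsemble:
    """Precomputed spherical rotations and their vertex reassignments.

    Under spin ``s``, vertex ``v`` reads the value of ``reindex[s, v]``.
    """

    rotations: np.ndarray  # (n, 3, 3)
    reindex: np.ndarray  # (n, V)
    seed: int
    surface: CorticalSurface

    @property
    def n_spins(self) -> int:
        return len(self.rotations)

    def apply(self, values: np.ndarray, s: int) -> np.ndarray:
        return np.asarray(values)[..., self.reindex[s]]


def make_spins(
    surface: CorticalSurface, n_spins: int, seed: int = 0, include_identity: bool = False
) -> SpinEnsemble:
    """Draw uniform SO(3) rotations and cache nearest-vertex reassignments."""
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_spins, random_state=rng).as_matrix()
    if include_identity:
        rots[0] = np.eye(3)
    tree = surface.sphere_kdtree()
    reindex = np.empty((n_spins, surface.n_vertices), dtype=np.int32)
    for s in range(n_spins):
        rotated = surface.sphere @ rots[s].T
        _, reindex[s] = tree.query(rotated, workers=-1)
    return SpinEnsemble(rotations=rots, reindex=reindex, seed=seed, surface=surface)


# ---------------------------------------------------------------- statistics
def _pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x**2).sum() * (y**2).sum())
    if den == 0:
        return np.nan
    return float((x * y).sum() / den)


def _delta_z(mask_x, y):
    z = (y - y.mean()) / y.std()
    if mask_x.all() or (~mask_x).all():
        return np.nan
    return float(z[mask_x].mean() - z[~mask_x].mean())


def _dice(a, b):
    s = a.sum() + b.sum()
    if s == 0:
        return np.nan
    return float(2.0 * (a & b).sum() / s)


def map_statistic(x, y, statistic: str) -> float:
    """Evaluate a two-map comparison statistic over defined vertices."""
    if statistic == "pearson":
        return _pearson(x, y)
    if statistic == "spearman":
        return _pearson(rankdata(x), rankdata(y))
    if statistic == "dice":
        return _dice(x.astype(bool), y.astype(bool))
    if statistic == "delta_z":
        return _delta_z(x.astype(bool), y)
    raise ValueError(f"unknown statistic {statistic!r}")


def spin_test(
    x,
    y,
    statistic: str,
    ensemble: SpinEnsemble,
    tail: str = "two",
):
    """Spin test between two maps (or tangent fields, via ``angle_skew``).

    The first argument is spun; the second stays fixed. Returns
    ``(observed, p_spin)``. Degenerate statistics (zero variance) return NaN
    with an explicit flag via a raised ``ValueError`` only when the observed
    statistic itself is undefined.
    """
    surface = ensemble.surface
    if statistic == "angle_skew":
        return _angle_skew_spin(x, y, ensemble, tail)
    xv = asvalues(x)
    yv = asvalues(y)
    mask = surface.cortex_mask & np.isfinite(xv) & np.isfinite(yv)
    obs = map_statistic(xv[mask], yv[mask], statistic)
    if not np.isfinite(obs):
        raise ValueError("degenerate statistic on the observed pair (zero variance?)")
    null = np.empty(ensemble.n_spins)
    for s in range(ensemble.n_spins):
        xs = ensemble.apply(xv, s)
        m = mask & np.isfinite(xs)
        null[s] = map_statistic(xs[m], yv[m], statistic)
    return obs, _pvalue(obs, null, tail)


def _pvalue(obs: float, null: np.ndarray, tail: str) -> float:
    null = null[np.isfinite(null)]
    n = len(null)
    if tail == "greater":
        k = (null >= obs).sum()
    elif tail == "less":
        k = (null <= obs).sum()
    elif tail == "two":
        k = (np.abs(null) >= abs(obs)).sum()
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1.0 + k) / (1.0 + n)


# ------------------------------------------------------- tangent-field spins
def spin_tangent_field(
    field: TangentField, ensemble: SpinEnsemble, s: int
) -> TangentField:
    """Rotate a tangent field with spin ``s``, transporting directions.

    Vertex ``v`` reads the vector at ``u = reindex[s, v]``: the 3-D vector at
    ``u`` is rotated by the spin rotation, projected into ``v``'s tangent
    plane, and re-expressed in ``v``'s tangent basis. This is the natural
    parallel transport of an axial direction through the rotation.
    """
    surface = ensemble.surface
    R = ensemble.rotations[s]
    src = ensemble.reindex[s]
    v3 = field.vectors3d()[src] @ R.T
    tb = surface.tangent_basis(field.geometry)
    coeffs = np.column_stack([(v3 * tb[:, 0]).sum(1), (v3 * tb[:, 1]).sum(1)])
    return TangentField(coeffs, surface, field.geometry)


def angle_between_fields(a: TangentField, b: TangentField) -> np.ndarray:
    """Axial angle in degrees in [0, 90] per vertex; NaN where undefined."""
    oa, ob = a.orientation, b.orientation
    d = np.abs(oa - ob) % 180.0
    return np.minimum(d, 180.0 - d)


def _angle_skew_spin(a: TangentField, b: TangentField, ensemble: SpinEnsemble, tail: str):
    ang = angle_between_fields(a, b)
    valid = np.isfinite(ang) & ensemble.surface.cortex_mask
    obs = skew(ang[valid], bias=False)
    null = np.empty(ensemble.n_spins)
    for s in range(ensemble.n_spins):
        aspun = spin_tangent_field(a, ensemble, s)
        angs = angle_between_fields(aspun, b)
        m = np.isfinite(angs) & ensemble.surface.cortex_mask
        null[s] = skew(angs[m], bias=False)
    return obs, _pvalue(obs, null, "greater" if tail == "two" else tail)


# ------------------------------------------------------------ max statistics
def max_stat_threshold(
    maps: np.ndarray,
    ensemble: SpinEnsemble,
    stat_fn=None,
    n_perm: int | None = None,
    quantile: float = 0.95,
    seed: int = 0,
):
    """Family-wise threshold from independent per-gene spins.

    ``maps`` is a (G, V) stack of per-gene maps; per permutation every row is
    spun by an independently drawn ensemble member, the per-vertex statistic
    (default: mean over genes) is recomputed, and its maximum over unmasked
    vertices recorded. The threshold is the given quantile of those maxima.

    Returns ``(threshold, maxima)``.
    """
    if stat_fn is None:
        stat_fn = lambda Z: Z.mean(axis=0)
    maps = np.asarray(maps, dtype=float)
    G = maps.shape[0]
    mask = ensemble.surface.cortex_mask
    n_perm = n_perm or ensemble.n_spins
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    filled = np.where(np.isfinite(maps), maps, 0.0)
    for p in range(n_perm):
        picks = rng.integers(0, ensemble.n_spins, size=G)
        spun = filled[np.arange(G)[:, None], ensemble.reindex[picks]]
        stat = stat_fn(spun)
        maxima[p] = np.nanmax(stat[mask])
    return float(np.quantile(maxima, quantile)), maxima


# ------------------------------------------------- spun + interpolated nulls
def rotate_donor_samples(donor, surface: CorticalSurface, R: np.ndarray,
                         max_dist_mm: float = 20.0):
    """Move a donor's retained samples by a rotation of the sphere.

    Samples are first mapped to vertices and collapsed (duplicates averaged);
    each sample vertex is then reassigned to the nearest vertex of its rotated
    spherical position. The per-gene multiset of sample values is unchanged.
    """
    from .dem import collapse_samples, map_samples

    vertex_idx, keep = map_samples(donor, surface, max_dist_mm)
    sv, vals = collapse_samples(donor.expr[:, keep], vertex_idx[keep])
    _, new_sv = surface.sphere_kdtree().query(surface.sphere[sv] @ np.asarray(R).T,
                                              workers=-1)
    return type(donor)(
        donor_id=donor.donor_id,
        sex=donor.sex,
        sample_coords=surface.vertices[new_sv],
        expr=vals,
        gene_ids=list(donor.gene_ids),
    )


def spun_interpolated_null(
    donors: list,
    surface: CorticalSurface,
    n_null: int = 10,
    fwhm_mm: float = 20.0,
    seed: int = 0,
    max_dist_mm: float = 20.0,
    rotations=None,
):
    """Null DEM libraries built by rotating sample locations before interpolation.

    For each null and donor, the donor's retained sample vertices are moved by
    one random rotation of the sphere (values travel with their samples), then
    the full interpolate -> smooth -> z-score -> average pipeline runs. The
    per-gene multiset of pre-interpolation sample values is preserved exactly.
    ``rotations`` can supply explicit per-null, per-donor 3x3 matrices.
    """
    from .dem import DEMLibrary, build_dems, collapse_samples, map_samples

    rng = np.random.default_rng(seed)
    tree = surface.sphere_kdtree()
    out = []
    for inull in range(n_null):
        rotated_donors = []
        for idonor, donor in enumerate(donors):
            if rotations is not None:
                R = np.asarray(rotations[inull][idonor])
            else:
                R = Rotation.random(random_state=rng).as_matrix()
            rotated_donors.append(
                rotate_donor_samples(donor, surface, R, max_dist_mm)
            )
        out.append(build_dems(rotated_donors, surface, fwhm_mm, max_dist_mm=np.inf))
    return out


# ----------------------------------------------------------- GLM + clusters
def _cluster_sizes(adj: sp.csr_matrix, suprathreshold: np.ndarray):
    nodes = np.flatnonzero(suprathreshold)
    if nodes.size == 0:
        return np.array([], dtype=int), np.full(len(suprathreshold), -1)
    sub = adj[np.ix_(nodes, nodes)]
    ncomp, comp = csgraph.connected_components(sub, directed=False)
    sizes = np.bincount(comp)
    labels = np.full(len(suprathreshold), -1)
    labels[nodes] = comp
    return sizes, labels


def glm_cluster_correction(
    Y: np.ndarray,
    design: np.ndarray,
    contrast_col: int,
    surface: CorticalSurface,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Vertex-wise OLS with cluster-extent permutation correction.

    ``Y`` is subjects x V, ``design`` subjects x p (including intercept), and
    ``contrast_col`` the column tested (e.g. group). Per-vertex t statistics
    are thresholded at ``alpha`` (two-sided), suprathreshold vertices grouped
    into edge-connected clusters, and clusters larger than the 95th percentile
    of the permutation-null maximum significant-cluster size are retained.
    Permutation follows the Freedman-Lane scheme: residuals from the reduced
    model (without the tested column) are permuted.

    Returns a dict with ``beta``, ``t``, ``p``, ``cluster_label`` (-1 outside
    retained clusters), and ``null_max_sizes``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X.T)
        bad = [
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"design is rank-deficient (collinear columns: {bad})")
    mask = surface.cortex_mask
    adj = surface.adjacency(weighted=False)

    pinv = np.linalg.pinv(X)
    dof = n - p
    xtx_inv_cc = np.linalg.inv(X.T @ X)[contrast_col, contrast_col]

    def t_map(Ymat):
        beta = pinv @ Ymat
        resid = Ymat - X @ beta
        sigma2 = (resid**2).sum(0) / dof
        se = np.sqrt(sigma2 * xtx_inv_cc)
        with np.errstate(invalid="ignore", divide="ignore"):
            return beta, np.where(se > 0, beta[contrast_col] / se, 0.0)

    beta, tobs = t_map(Y)
    pvals = 2 * t_dist.sf(np.abs(tobs), dof)
    supra = (pvals < alpha) & mask
    obs_sizes, obs_labels = _cluster_sizes(adj, supra)

    # Freedman-Lane: reduced model without the tested column
    Z = np.delete(X, contrast_col, axis=1)
    pinv_z = np.linalg.pinv(Z)
    fitted_red = Z @ (pinv_z @ Y)
    resid_red = Y - fitted_red

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        Ystar = fitted_red + resid_red[perm]
        _, tstar = t_map(Ystar)
        pstar = 2 * t_dist.sf(np.abs(tstar), dof)
        sizes, _ = _cluster_sizes(adj, (pstar < alpha) & mask)
        null_max[i] = sizes.max(initial=0)
    size_thr = np.quantile(null_max, 0.95)

    cluster_label = np.full(surface.n_vertices, -1)
    kept = 0
    for c, size in enumerate(obs_sizes):
        if size > size_thr:
            cluster_label[obs_labels == c] = kept
            kept += 1
    return {
        "beta": beta,
        "t": tobs,
        "p": pvals,
        "cluster_label": cluster_label,
        "n_clusters": kept,
        "null_max_sizes": null_max,
        "size_threshold": float(size_thr),
    }


# -------------------------------------------------------- parcel-level spins
def parcel_means(values: np.ndarray, parcellation: np.ndarray, parcel_ids) -> np.ndarray:
    return np.array(
        [np.nanmean(values[parcellation == pid]) for pid in parcel_ids]
    )


def parcel_spin_correlation(
    m,
    parcel_values: dict,
    parcellation: np.ndarray,
    ensemble: SpinEnsemble,
    statistic: str = "pearson",
):
    """Correlate a vertex map, aggregated to parcels, with per-parcel values.

    The null spins the vertex map and re-aggregates parcel means each time.
    """
    vals = asvalues(m)
    pids = sorted(parcel_values)
    if len(pids) < 2:
        raise ValueError("need at least two parcels")
    target = np.array([parcel_values[p] for p in pids])
    obs = map_statistic(parcel_means(vals, parcellation, pids), target, statistic)
    null = np.empty(ensemble.n_spins)
    for s in range(ensemble.n_spins):
        null[s] = map_statistic(
            parcel_means(ensemble.apply(vals, s), parcellation, pids), target, statistic
        )
    return obs, _pvalue(obs, null, "two")
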