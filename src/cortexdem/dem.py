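"""Building dense expression map (DEM) libraries from sparse donor samples.

The pipeline per donor and gene: map samples to their nearest cortical
vertices (excluding samples too far from the surface), propagate sampled
values to every vertex by nearest-neighbor interpolation on the spherical
projection, smooth with a geodesic Gaussian kernel, and z-score across
unmasked vertices. Donor maps are then averaged gene-wise, with Y-chromosome
genes drawn from male donors only. Per-donor z-scoring removes affine donor
effects (scale and shift) by construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .surface import CorticalSurface, smooth_map

logger = logging.getLogger(__name__)

__all__ = [
    "DonorExpression",
    "DEMLibrary",
    "SamplingStats",
    "map_samples",
    "nn_interpolate",
    "build_dems",
    "sampling_stats",
    "split_reproducibility",
    "fit_learning_curve",
]


@dataclass
class DonorExpression:
    """One donor's gene x sample expression matrix with sample coordinates."""

    donor_id: str
    sex: str
    sample_coords: np.ndarray  # (S, 3) mm
    expr: np.ndarray  # (G, S)
    gene_ids: list

    def __post_init__(self):
        self.sample_coords = np.asarray(self.sample_coords, dtype=float)
        self.expr = np.asarray(self.expr, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if self.expr.shape != (len(self.gene_ids), len(self.sample_coords)):
            raise ValueError("expr shape does not match gene_ids x samples")
        if not np.all(np.isfinite(self.expr)):
            raise ValueError("expr must be finite")


@dataclass
class DEMLibrary:
    """Gene x vertex z-scored dense expression maps, averaged over donors."""

    gene_ids: list
    z: np.ndarray  # (G, V)
    surface: CorticalSurface
    fwhm_mm: float = 20.0
    n_donors_per_gene: np.ndarray = None
    reproducibility: np.ndarray = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.n_donors_per_gene is None:
            self.n_donors_per_gene = np.ones(len(self.gene_ids), dtype=int)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)


@dataclass
class SamplingStats:
    """Sampling density rho (samples/mm^2) and inferred inter-sample distance."""

    rho: float
    d_mm: float
    n_used: int
    n_excluded: int


def map_samples(
    donor: DonorExpression, surface: CorticalSurface, max_dist_mm: float = 20.0
):
    """Assign each sample to its nearest unmasked vertex (Euclidean distance).

    Samples farther than ``max_dist_mm`` from every unmasked vertex are
    excluded. Returns ``(vertex_idx, keep)`` where ``vertex_idx[i]`` is the
    assigned vertex for each retained sample. Ties go to the lowest vertex
    index.
    """
    unmasked = np.flatnonzero(surface.cortex_mask)
    # full argmin keeps the lowest-index tie-break exact
    d2 = (
        ((donor.sample_coords[:, None, :] - surface.vertices[None, unmasked, :]) ** 2)
        .sum(-1)
    )
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(nearest)), nearest])
    keep = dist <= max_dist_mm
    if not keep.any():
        raise ValueError("no samples within max_dist_mm of the surface")
    return unmasked[nearest], keep


def collapse_samples(values: np.ndarray, vertex_idx: np.ndarray):
    """Average values of samples assigned to the same vertex.

    ``values`` is (G, S); returns (unique_vertices, (G, S') means).
    """
    uniq, inv = np.unique(vertex_idx, return_inverse=True)
    sums = np.zeros((values.shape[0], uniq.size))
    counts = np.bincount(inv, minlength=uniq.size)
    np.add.at(sums.T, inv, values.T)
    return uniq, sums / counts


def nn_interpolate(
    sampled_vertices: np.ndarray, values: np.ndarray, surface: CorticalSurface
) -> np.ndarray:
    """Propagate values at sampled vertices to all vertices.

    Every unmasked vertex takes the value of its nearest sampled vertex
    measured by great-circle distance on the spherical projection (chord
    distance gives the same ordering). ``values`` may be (S',) or (G, S').
    Ties resolve to the lowest sampled-vertex index. Masked vertices are NaN.
    """
    sampled_vertices = np.asarray(sampled_vertices, dtype=int)
    if sampled_vertices.size == 0:
        raise ValueError("need at least one sampled vertex")
    order = np.argsort(sampled_vertices)  # ascending → argmin tie = lowest index
    sv = sampled_vertices[order]
    vals = np.asarray(values, dtype=float)[..., order]
    arc = np.arccos(np.clip(surface.sphere @ surface.sphere[sv].T, -1.0, 1.0))
    nearest = np.argmin(arc, axis=1)
    out = vals[..., nearest]
    out[..., ~surface.cortex_mask] = np.nan
    return out


def _zscore_rows(x: np.ndarray, mask: np.ndarray):
    """Population (n) z-score across unmasked vertices; returns (z, sd).

    The returned sd is zeroed where it is negligible relative to the map's
    magnitude, so numerically-flat maps are treated as zero-variance.
    """
    sub = x[..., mask]
    mu = sub.mean(axis=-1, keepdims=True)
    sd = sub.std(axis=-1, keepdims=True)
    flat = sd <= 1e-12 * (np.abs(mu) + 1.0)
    sd = np.where(flat, 0.0, sd)
    safe = np.where(sd == 0, 1.0, sd)
    return (x - mu) / safe, sd.squeeze(-1)


def build_dems(
    donors: list,
    surface: CorticalSurface,
    fwhm_mm: float = 20.0,
    max_dist_mm: float = 20.0,
    gene_chromosome: dict | None = None,
) -> DEMLibrary:
    """Build a DEM library: interpolate, smooth, z-score, average over donors.

    The gene universe is the intersection across donors (a warning is logged
    when genes are lost). Y-chromosome genes (per ``gene_chromosome``) use
    male donors only. A gene with zero variance within a donor contributes no
    map from that donor.
    """
    if not donors:
        raise ValueError("no donors given")
    genes = set(donors[0].gene_ids)
    for d in donors[1:]:
        genes &= set(d.gene_ids)
    gene_ids = [g for g in donors[0].gene_ids if g in genes]
    if len(gene_ids) < max(len(d.gene_ids) for d in donors):
        logger.warning(
            "gene universe reduced to %d genes (intersection across donors)", len(gene_ids)
        )
    G, V = len(gene_ids), surface.n_vertices
    mask = surface.cortex_mask

    acc = np.zeros((G, V))
    n_per_gene = np.zeros(G, dtype=int)
    is_y = np.array(
        [(gene_chromosome or {}).get(g, "") in ("Y", "chrY") for g in gene_ids]
    )
    for donor in donors:
        idx = [donor.gene_ids.index(g) for g in gene_ids]
        vertex_idx, keep = map_samples(donor, surface, max_dist_mm)
        sv, vals = collapse_samples(donor.expr[idx][:, keep], vertex_idx[keep])
        maps = nn_interpolate(sv, vals, surface)
        maps = smooth_map(maps, surface, fwhm_mm)
        z, sd = _zscore_rows(maps, mask)
        usable = sd > 0
        if not usable.all():
            logger.warning(
                "donor %s: %d zero-variance genes skipped", donor.donor_id, (~usable).sum()
            )
        if donor.sex != "M":
            usable = usable & ~is_y
        acc[usable] += np.where(np.isfinite(z[usable]), z[usable], 0.0)
        n_per_gene += usable
    with np.errstate(invalid="ignore", divide="ignore"):
        z = acc / n_per_gene[:, None]
    z[:, ~mask] = np.nan
    return DEMLibrary(
        gene_ids=gene_ids, z=z, surface=surface, fwhm_mm=fwhm_mm,
        n_donors_per_gene=n_per_gene,
    )


def sampling_stats(
    donor: DonorExpression, surface: CorticalSurface, max_dist_mm: float = 20.0
) -> SamplingStats:
    """Sampling density rho = retained samples / unmasked area; d = 1/sqrt(rho)."""
    _, keep = map_samples(donor, surface, max_dist_mm)
    area = float(surface.vertex_area[surface.cortex_mask].sum())
    rho = keep.sum() / area
    return SamplingStats(
        rho=rho, d_mm=1.0 / np.sqrt(rho), n_used=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )


def disjoint_subset_pairs(n_donors: int, subset_size: int):
    """All unordered pairs of disjoint donor-index subsets of a given size."""
    pairs = set()
    idx = range(n_donors)
    for a in itertools.combinations(idx, subset_size):
        rest = [i for i in idx if i not in a]
        for b in itertools.combinations(rest, subset_size):
            pairs.add(tuple(sorted((a, b))))
    return sorted(pairs)


def split_reproducibility(
    donors: list,
    surface: CorticalSurface,
    subset_size: int = 3,
    fwhm_mm: float = 20.0,
    **build_kwargs,
):
    """Gene- and vertex-level reproducibility between disjoint donor subsets.

    For every unordered pair of disjoint subsets of the given size (six
    donors split into triplets give exactly 10 such pairs), sub-libraries are
    built independently and compared: per gene, the Pearson correlation of
    its two maps across unmasked vertices; per vertex, the Spearman
    correlation of the two gene-expression rankings at that vertex.

    Returns a dict with pooled ``gene_r`` (n_splits, G), ``vertex_r``
    (n_splits, V), and the ``splits`` inventory.
    """
    n = len(donors)
    if subset_size < 1 or 2 * subset_size > n:
        raise ValueError("subset_size out of range")
    pairs = disjoint_subset_pairs(n, subset_size)
    cache: dict[tuple, DEMLibrary] = {}

    def lib(subset):
        if subset not in cache:
            cache[subset] = build_dems(
                [donors[i] for i in subset], surface, fwhm_mm, **build_kwargs
            )
        return cache[subset]

    mask = surface.cortex_mask
    gene_r, vertex_r = [], []
    for a, b in pairs:
        za, zb = lib(a).z[:, mask], lib(b).z[:, mask]
        gene_r.append(_rowwise_pearson(za, zb))
        ra = rankdata(za, axis=0)
        rb = rankdata(zb, axis=0)
        vr = np.full(surface.n_vertices, np.nan)
        vr[mask] = _rowwise_pearson(ra.T, rb.T)
        vertex_r.append(vr)
    return {
        "gene_r": np.asarray(gene_r),
        "vertex_r": np.asarray(vertex_r),
        "splits": pairs,
    }


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(1)
    den = np.sqrt((a**2).sum(1) * (b**2).sum(1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def fit_learning_curve(sizes, mean_r, extrapolate_to: int):
    """Fit r(n) = a - b * n^(-c) and extrapolate reproducibility.

    Nonlinear least squares with a clamped to [-1, 1] and b, c positive.
    Returns ``(a, b, c, predicted_r, converged)``; on non-convergence a
    monotone fallback (a = max observed r extrapolated flat) is flagged.
    """
    sizes = np.asarray(sizes, dtype=float)
    mean_r = np.asarray(mean_r, dtype=float)
    if len(np.unique(sizes)) < 3:
        raise ValueError("need at least 3 distinct sizes")

    def f(n, a, b, c):
        return a - b * n ** (-c)

    try:
        p0 = (min(max(mean_r.max(), -1.0), 1.0), max(mean_r.max() - mean_r.min(), 1e-3), 1.0)
        popt, _ = curve_fit(
            f, sizes, mean_r, p0=p0,
            bounds=([-1, 1e-12, 1e-12], [1, np.inf, np.inf]), maxfev=20000,
        )
        a, b, c = popt
        return a, b, c, f(float(extrapolate_to), a, b, c), True
    except RuntimeError:
        a = float(mean_r.max())
        return a, 0.0, 1.0, a, False
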