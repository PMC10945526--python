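"""Spatial co-expression modules over vertices (WGCNA-style pipeline).

Gene-gene spatial correlations across vertices are soft-thresholded into a
signed adjacency a = ((1 + r) / 2)^beta, with beta chosen as the smallest
power giving a scale-free topology fit r^2 > 0.8. The topological overlap
matrix (TOM) measures shared network neighborhoods; 1 - TOM is clustered by
average-linkage hierarchical clustering with a static cut, modules below the
minimum size are left unassigned, each module is summarized by its eigenmap
(first PC of member expression across vertices), near-duplicate modules
(eigenmap correlation > 0.9) are merged, and modules enriched for
non-cortically-expressed genes are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as hier
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from .dem import DEMLibrary

__all__ = [
    "ModuleSet",
    "gene_correlation",
    "soft_adjacency",
    "pick_soft_power",
    "compute_tom",
    "cut_modules",
    "module_eigenmaps",
    "merge_similar",
    "compute_kme",
    "drop_noncortical",
    "detect_modules",
]


@dataclass
class ModuleSet:
    """Gene-to-module assignment with eigenmaps and membership strengths.

    ``assignment[g]`` is 0 for unassigned genes, else the 1-based module id.
    ``eigenmaps`` is (M, V), z-scored across unmasked vertices; ``kme`` is
    (G, M) Pearson correlations between gene maps and eigenmaps.
    """

    gene_ids: list
    assignment: np.ndarray
    eigenmaps: np.ndarray
    kme: np.ndarray
    soft_power: int = 6
    min_size: int = 30
    merge_log: list = field(default_factory=list)

    @property
    def module_ids(self) -> list:
        return sorted(set(self.assignment[self.assignment > 0].tolist()))

    def genes_in(self, module: int) -> list:
        return [g for g, a in zip(self.gene_ids, self.assignment) if a == module]


def gene_correlation(library: DEMLibrary) -> np.ndarray:
    """Gene x gene Pearson correlation across unmasked vertices."""
    z = library.z[:, library.surface.cortex_mask]
    r = np.corrcoef(z)
    return np.clip(np.nan_to_num(r), -1.0, 1.0)


def soft_adjacency(corr: np.ndarray, power: int) -> np.ndarray:
    """Signed soft-thresholded adjacency a = ((1 + r) / 2)^beta, zero diagonal."""
    a = ((1.0 + corr) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return np.nan
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_power(
    corr: np.ndarray, powers=range(1, 21), target_r2: float = 0.8
):
    """Smallest soft power whose network is scale-free (signed fit > target).

    Returns ``(power, fit_table, reached_target)``; if no power reaches the
    target, the best-fitting power is returned with a warning flag.
    """
    fits = {}
    for beta in powers:
        a = soft_adjacency(corr, beta)
        fits[beta] = _scale_free_fit(a.sum(axis=1))
    for beta in powers:
        if np.isfinite(fits[beta]) and fits[beta] > target_r2:
            return beta, fits, True
    finite = {b: f for b, f in fits.items() if np.isfinite(f)}
    best = max(finite, key=finite.get) if finite else list(powers)[0]
    return best, fits, False


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: omega_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = np.asarray(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom)
    np.fill_diagonal(tom, 1.0)
    return np.clip(0.5 * (tom + tom.T), 0.0, 1.0)


def cut_modules(
    tom: np.ndarray,
    min_size: int = 30,
    cut_height: float | None = None,
) -> np.ndarray:
    """Average-linkage modules from 1 - TOM with a static tree cut.

    The default cut height is the lowest height at which the number of
    clusters of at least ``min_size`` genes is maximal -- the point where
    every tight co-expression module has formed a core but unstructured
    genes have not yet agglomerated onto them. The cores are deliberately
    conservative: full module membership is recovered downstream by kME
    classification (see :func:`reassign_by_kme`). A fixed ``cut_height``
    can be given instead. Clusters smaller than ``min_size`` are unassigned
    (0); modules are relabeled 1..M by decreasing size (ties by first gene).
    """
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    linkage = hier.linkage(squareform(d, checks=False), method="average")

    def cut_at(height):
        raw = hier.fcluster(linkage, t=height, criterion="distance")
        assignment = np.zeros(len(raw), dtype=int)
        labels, counts = np.unique(raw, return_counts=True)
        keep = labels[counts >= min_size]
        order = sorted(
            keep,
            key=lambda lab: (-int((raw == lab).sum()), int(np.argmax(raw == lab))),
        )
        for new, lab in enumerate(order, start=1):
            assignment[raw == lab] = new
        return assignment

    if cut_height is not None:
        return cut_at(cut_height)
    heights = np.unique(linkage[:, 2])
    candidates = np.quantile(heights, np.linspace(0.02, 0.999, 80))
    best, best_n = None, -1
    for t in candidates:
        assignment = cut_at(t)
        n = assignment.max()
        if n > best_n:  # lowest height achieving the maximal module count
            best, best_n = assignment, n
    return best


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def module_eigenmaps(library: DEMLibrary, assignment: np.ndarray) -> np.ndarray:
    """First PC across vertices of each module's member genes, as maps.

    Sign-oriented so the mean correlation with member genes is positive,
    then z-scored across unmasked vertices. Returns (M, V) with NaN outside
    the mask.
    """
    mask = library.surface.cortex_mask
    V = library.surface.n_vertices
    modules = sorted(set(assignment[assignment > 0].tolist()))
    out = np.full((len(modules), V), np.nan)
    for row, m in enumerate(modules):
        z = library.z[assignment == m][:, mask]
        zc = z - z.mean(axis=1, keepdims=True)
        # first right singular vector over vertices
        _, _, vt = np.linalg.svd(zc, full_matrices=False)
        pc = vt[0]
        corr = (zc @ pc) / (
            np.linalg.norm(zc, axis=1) * np.linalg.norm(pc) + 1e-300
        )
        if corr.mean() < 0:
            pc = -pc
        out[row, mask] = _zscore(pc)
    return out


def compute_kme(library: DEMLibrary, eigenmaps: np.ndarray) -> np.ndarray:
    """Pearson correlation of every gene map with every eigenmap, (G, M)."""
    mask = library.surface.cortex_mask
    z = library.z[:, mask]
    e = eigenmaps[:, mask]
    zc = z - z.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    num = zc @ ec.T
    den = np.outer(
        np.linalg.norm(zc, axis=1), np.linalg.norm(ec, axis=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.clip(num / den, -1.0, 1.0)


def _build_moduleset(library, assignment, soft_power, min_size, merge_log=None):
    eig = module_eigenmaps(library, assignment)
    kme = compute_kme(library, eig)
    return ModuleSet(
        gene_ids=list(library.gene_ids),
        assignment=assignment,
        eigenmaps=eig,
        kme=kme,
        soft_power=soft_power,
        min_size=min_size,
        merge_log=merge_log or [],
    )


def merge_similar(
    moduleset: ModuleSet, library: DEMLibrary, threshold: float = 0.9
) -> ModuleSet:
    """Iteratively merge module pairs whose eigenmaps correlate above threshold."""
    assignment = moduleset.assignment.copy()
    log = list(moduleset.merge_log)
    mask = library.surface.cortex_mask
    while True:
        modules = sorted(set(assignment[assignment > 0].tolist()))
        if len(modules) < 2:
            break
        eig = module_eigenmaps(library, assignment)
        r = np.corrcoef(eig[:, mask])
        np.fill_diagonal(r, -np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] <= threshold:
            break
        a, b = modules[i], modules[j]
        assignment[assignment == b] = a
        log.append((a, b, float(r[i, j])))
        # compact labels
        for new, m in enumerate(sorted(set(assignment[assignment > 0].tolist())), 1):
            assignment[assignment == m] = new
    return _build_moduleset(
        library, assignment, moduleset.soft_power, moduleset.min_size, log
    )


def drop_noncortical(
    moduleset: ModuleSet, library: DEMLibrary, ncexp_genes, alpha: float | None = None
) -> ModuleSet:
    """Remove modules significantly enriched for non-cortically-expressed genes.

    One-sided Fisher's exact enrichment of each module against the library
    background; ``alpha`` defaults to 0.05 / n_modules. Genes of removed
    modules become unassigned.
    """
    assignment = moduleset.assignment.copy()
    modules = sorted(set(assignment[assignment > 0].tolist()))
    if not modules:
        return moduleset
    if alpha is None:
        alpha = 0.05 / len(modules)
    nc = set(ncexp_genes)
    genes = np.asarray(moduleset.gene_ids)
    flagged = np.array([g in nc for g in genes])
    removed = []
    for m in modules:
        in_mod = assignment == m
        a = int((in_mod & flagged).sum())
        b = int((in_mod & ~flagged).sum())
        c = int((~in_mod & flagged).sum())
        d = int((~in_mod & ~flagged).sum())
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        if p < alpha:
            assignment[in_mod] = 0
            removed.append((m, p))
    if not removed:
        return moduleset
    for new, m in enumerate(sorted(set(assignment[assignment > 0].tolist())), 1):
        assignment[assignment == m] = new
    log = moduleset.merge_log + [("dropped_noncortical", removed)]
    return _build_moduleset(
        library, assignment, moduleset.soft_power, moduleset.min_size, log
    )


def reassign_by_kme(
    moduleset: ModuleSet, library: DEMLibrary, threshold: float = 0.3
) -> ModuleSet:
    """Classify every gene to its best-matching module by kME.

    Genes whose maximal |kME| falls below ``threshold`` are unassigned. This
    recovers full module membership from conservative cores and mirrors the
    use of kME as the module-membership measure.
    """
    kme = moduleset.kme
    best = np.argmax(np.abs(kme), axis=1)
    bestv = kme[np.arange(len(best)), best]
    assignment = np.where(bestv >= threshold, best + 1, 0)
    return _build_moduleset(
        library, assignment, moduleset.soft_power, 0, moduleset.merge_log
    )


def detect_modules(
    library: DEMLibrary,
    soft_power: int | None = None,
    min_size: int = 30,
    merge_threshold: float = 0.9,
    cut_height: float | None = None,
    kme_threshold: float | None = 0.3,
) -> ModuleSet:
    """Full pipeline: correlation -> soft power -> TOM -> cores -> eigenmaps
    -> merge -> kME classification.

    Set ``kme_threshold`` to None to skip the final membership step and
    return the merged cores directly.
    """
    corr = gene_correlation(library)
    if soft_power is None:
        soft_power, _, _ = pick_soft_power(corr)
    tom = compute_tom(soft_adjacency(corr, soft_power))
    assignment = cut_modules(tom, min_size=min_size, cut_height=cut_height)
    ms = _build_moduleset(library, assignment, soft_power, min_size)
    ms = merge_similar(ms, library, merge_threshold)
    if kme_threshold is not None and len(ms.module_ids):
        ms = reassign_by_kme(ms, library, kme_threshold)
    return ms
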