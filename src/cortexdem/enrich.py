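"""Gene-set statistics linking modules and peaks to annotations.

Fisher's exact enrichment with multiplicity control across modules,
degree-decile-matched protein-protein-interaction connectivity nulls,
developmental trajectory coherence, and community structure over pairwise
annotation-overlap networks. Enrichment tests are one-sided throughout
(enrichment, not depletion). Gene identifiers are harmonized by exact symbol
match; unmatched ids are dropped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "fisher_enrichment",
    "make_top_fraction_markers",
    "ppi_module_test",
    "trajectory_coherence_test",
    "annotation_graph",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with category tags over a background universe."""

    sets: dict  # name -> list of gene ids
    background: list
    category: dict = field(default_factory=dict)  # name -> tag

    def __post_init__(self):
        universe = set(self.background)
        cleaned = {}
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in universe]
            dropped = len(genes) - len(kept)
            if dropped:
                logger.warning("%s: %d gene ids outside the universe dropped", name, dropped)
            cleaned[name] = kept
        self.sets = cleaned


def _fisher_one(target: set, annot: set, universe: set):
    a = len(target & annot)
    b = len(target - annot)
    c = len(annot - target)
    d = len(universe) - a - b - c
    # one-sided enrichment p: hypergeometric upper tail
    p = float(hypergeom.sf(a - 1, len(universe), len(annot), len(target)))
    if b * c == 0 and a * d != 0:
        odds = np.inf
        haldane = False
    elif min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        haldane = True
    else:
        odds = (a * d) / (b * c)
        haldane = False
    return a, odds, p, haldane


def fisher_enrichment(
    targets: dict,
    annotations: dict,
    background,
    correction: str = "bonferroni_across_targets",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of every target set against every annotation.

    ``correction`` is either ``bonferroni_across_targets`` (the p < 0.05
    threshold divided by the number of target sets, the convention used when
    screening many modules against one annotation family) or ``holm_sidak``
    (step-down across all pairs). Returns a table with odds ratio, raw and
    adjusted p, both significance flags, and overlap genes.
    """
    universe = set(background)
    for name, genes in list(targets.items()) + list(annotations.items()):
        if not set(genes) <= universe:
            raise ValueError(f"gene set {name!r} is not contained in the background")
    rows = []
    for tname, tgenes in targets.items():
        t = set(tgenes)
        for aname, agenes in annotations.items():
            a = set(agenes)
            overlap, odds, p, haldane = _fisher_one(t, a, universe)
            rows.append(
                {
                    "target": tname,
                    "annotation": aname,
                    "overlap": overlap,
                    "odds_ratio": odds,
                    "haldane": haldane,
                    "p": p,
                    "overlap_genes": sorted(t & a),
                }
            )
    df = pd.DataFrame(rows)
    if correction == "bonferroni_across_targets":
        m = max(len(targets), 1)
        df["p_adjusted"] = np.minimum(df["p"] * m, 1.0)
    elif correction == "holm_sidak":
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(df["p"].to_numpy(), method="holm-sidak")
        df["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown correction {correction!r}")
    df["significant_pairwise"] = df["p"] < 0.05
    df["significant_corrected"] = df["p_adjusted"] < 0.05
    return df


def make_top_fraction_markers(
    expr: pd.DataFrame, fraction: float = 0.05
) -> dict:
    """Top-``fraction`` expressed genes per group (column) as marker sets.

    ``expr`` is genes x groups with gene ids as index. Ties at the cutoff are
    included, so sets may slightly exceed the nominal fraction (logged).
    """
    n = int(round(fraction * len(expr)))
    out = {}
    for col in expr.columns:
        v = expr[col]
        if n <= 0:
            out[col] = []
            continue
        cutoff = v.nlargest(n).min()
        members = v.index[v >= cutoff].tolist()
        if len(members) > n:
            logger.warning(
                "%s: ties at the cutoff expand the marker set to %d genes", col, len(members)
            )
        out[col] = members
    return out


def ppi_module_test(
    module_genes,
    ppi_edges,
    n_resample: int = 10000,
    seed: int = 0,
):
    """Degree-decile-matched test of intramodular PPI connectivity.

    The observed statistic is the median within-module degree of module genes
    in the PPI graph. Null modules resample genes from the same global-degree
    deciles as the module's members (exactly matching its decile profile).

    Returns a dict with ``median_degree``, ``p``, ``n_present``, and an
    ``underpowered`` flag when fewer than 5 module genes are in the network.
    """
    edges = [(str(u), str(v)) for u, v in ppi_edges if u != v]
    nodes = sorted({u for e in edges for u in e})
    index = {g: i for i, g in enumerate(nodes)}
    deg = np.zeros(len(nodes), dtype=int)
    nbrs = [set() for _ in nodes]
    for u, v in edges:
        iu, iv = index[u], index[v]
        if iv not in nbrs[iu]:
            nbrs[iu].add(iv)
            nbrs[iv].add(iu)
            deg[iu] += 1
            deg[iv] += 1

    present = [index[g] for g in module_genes if g in index]
    absent = len(list(module_genes)) - len(present)
    if absent:
        logger.warning("%d module genes absent from the PPI network", absent)
    underpowered = len(present) < 5

    # decile assignment over all network nodes by degree rank
    order = np.argsort(np.argsort(deg, kind="stable"), kind="stable")
    decile = (order * 10) // len(nodes)
    by_decile = [np.flatnonzero(decile == d) for d in range(10)]

    present_set = set(present)

    def median_intramodular(members):
        mem = set(members)
        return float(np.median([len(nbrs[i] & mem) for i in members])) if members else 0.0

    obs = median_intramodular(list(present_set))
    profile = np.bincount(decile[present], minlength=10)
    rng = np.random.default_rng(seed)
    null = np.empty(n_resample)
    for r in range(n_resample):
        draw = []
        for d in range(10):
            if profile[d]:
                draw.extend(
                    rng.choice(by_decile[d], size=profile[d], replace=False).tolist()
                )
        null[r] = median_intramodular(draw)
    p = (1.0 + (null >= obs).sum()) / (1.0 + n_resample)
    return {
        "median_degree": obs,
        "p": float(p),
        "n_present": len(present),
        "underpowered": underpowered,
        "null": null,
    }


def _trajectory_matrix(
    genes, trajectories: dict, n_points: int = 20
) -> np.ndarray:
    """Smooth each gene's (age, value) series and sample 20 log-age points.

    A GCV-penalized cubic smoothing spline over log-age, evaluated at equally
    spaced points in log time and z-normalized per gene.
    """
    from scipy.interpolate import make_smoothing_spline

    rows = []
    for g in genes:
        age, val = trajectories[g]
        age = np.asarray(age, dtype=float)
        val = np.asarray(val, dtype=float)
        order = np.argsort(age)
        la = np.log(age[order])
        grid = np.linspace(la.min(), la.max(), n_points)
        try:
            spl = make_smoothing_spline(la, val[order])
            y = spl(grid)
        except Exception:
            y = np.interp(grid, la, val[order])
        sd = y.std()
        rows.append((y - y.mean()) / (sd if sd > 0 else 1.0))
    return np.asarray(rows)


def trajectory_coherence_test(
    module_genes,
    trajectories: dict,
    n_resample: int = 1000,
    seed: int = 0,
):
    """Do module genes share a developmental expression trajectory?

    Observed statistic: median pairwise Pearson correlation between the
    module genes' smoothed, z-normalized trajectories (20 log-age points).
    Null: size-matched random gene sets from all genes with trajectories.
    """
    all_genes = sorted(trajectories)
    members = [g for g in module_genes if g in trajectories]
    if len(members) < 2:
        raise ValueError("need at least two module genes with trajectories")
    Z = _trajectory_matrix(all_genes, trajectories)
    index = {g: i for i, g in enumerate(all_genes)}

    def median_pairwise(idx):
        r = np.corrcoef(Z[idx])
        iu = np.triu_indices(len(idx), 1)
        return float(np.median(r[iu]))

    obs = median_pairwise([index[g] for g in members])
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            median_pairwise(rng.choice(len(all_genes), size=len(members), replace=False))
            for _ in range(n_resample)
        ]
    )
    p = (1.0 + (null >= obs).sum()) / (1.0 + n_resample)
    return {"median_r": obs, "p": float(p), "n_genes": len(members), "null": null}


def annotation_graph(
    pmatrix: pd.DataFrame,
    p_cap: float = 0.1,
    edge_p: float = 0.05,
    drop_fraction: float = 0.1,
    seed: int = 0,
    n_restarts: int = 10,
):
    """Annotation-similarity network with Louvain communities.

    Pairwise enrichment p-values above ``p_cap`` are set to 1, weights are
    -log10(p), node degree is counted over edges with p < ``edge_p``, the
    lowest-degree ``drop_fraction`` of nodes is excluded, and Louvain
    clustering (best modularity over restarts) partitions the rest.

    Returns a dict with ``weights`` (DataFrame), ``kept`` nodes, and
    ``communities`` (node -> community id).
    """
    import networkx as nx

    P = pmatrix.copy().astype(float)
    P.values[P.values > p_cap] = 1.0
    np.fill_diagonal(P.values, 1.0)
    W = -np.log10(P.values)
    names = list(P.index)

    degree = ((P.values < edge_p).sum(axis=1))
    order = np.argsort(degree, kind="stable")
    n_drop = int(np.floor(drop_fraction * len(names)))
    dropped = set(order[:n_drop].tolist()) if n_drop else set()
    kept = [i for i in range(len(names)) if i not in dropped]

    G = nx.Graph()
    G.add_nodes_from(names[i] for i in kept)
    for ii, i in enumerate(kept):
        for j in kept[ii + 1 :]:
            if W[i, j] > 0:
                G.add_edge(names[i], names[j], weight=W[i, j])

    best, best_q = None, -np.inf
    for r in range(n_restarts):
        if G.number_of_edges() == 0:
            best = []
            break
        comms = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        q = nx.community.modularity(G, comms, weight="weight")
        if q > best_q:
            best, best_q = comms, q
    communities = {}
    for cid, comm in enumerate(best or []):
        for node in comm:
            communities[node] = cid
    return {
        "weights": pd.DataFrame(W, index=names, columns=names),
        "kept": [names[i] for i in kept],
        "communities": communities,
    }
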