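"""Annotate the co-expression modules: Fisher enrichment against the planted
marker sets, PPI connectivity with degree-decile-matched nulls, trajectory
coherence, and the annotation-similarity network.

The synthetic annotations play the roles of the study's marker-set families:
the planted per-module marker sets should light up on the diagonal, the PPI
test should detect a clique planted on one module's genes, and trajectory
coherence should flag the module whose genes were given a shared
developmental time course.

Reads results/dataset/ and results/modules/; writes results/enrichment/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import cortexdem as cd
from cortexdem.dataset import read_dataset

SEED = 20240907
rng = np.random.default_rng(SEED)

ds = read_dataset("results/dataset")
assign = pd.read_csv("results/modules/assignment.tsv", sep="\t")
genes = assign["gene"].tolist()
modules = {
    f"M{m}": assign.loc[assign["module_filtered"] == m, "gene"].tolist()
    for m in sorted(set(assign["module_filtered"])) if m > 0
}
annots = {k: v for k, v in ds["markers"].items() if k.startswith("module_")}

out = Path("results/enrichment")
out.mkdir(parents=True, exist_ok=True)

# ---- Fisher enrichment of detected modules vs planted marker sets ---------
table = cd.fisher_enrichment(modules, annots, genes, correction="bonferroni_across_targets")
table.drop(columns="overlap_genes").to_csv(out / "fisher.tsv", sep="\t", index=False)
diag = (
    table.loc[table["significant_corrected"]]
    .groupby("target")["annotation"]
    .apply(list)
    .to_dict()
)
print("modules with corrected-significant marker enrichment:", diag)

# ---- PPI connectivity: clique planted on the first module -----------------
m1 = modules[sorted(modules)[0]][:15]
edges = []
for i, n_genes in enumerate(genes):
    pass
others = [g for g in genes if g not in m1]
for u in range(len(genes)):
    for v in range(u + 1, len(genes)):
        if rng.random() < 0.01:
            edges.append((genes[u], genes[v]))
for i in range(len(m1)):
    for j in range(i + 1, len(m1)):
        edges.append((m1[i], m1[j]))
ppi = cd.ppi_module_test(m1, edges, n_resample=5000, seed=SEED)
print(f"PPI clique module: median intramodular degree {ppi['median_degree']:.0f}, "
      f"p = {ppi['p']:.2g}")

# ---- trajectory coherence: shared time course for the first module --------
ages = np.exp(np.linspace(np.log(70), np.log(23000), 15))
shared = np.sin(np.linspace(0, 3, 15))
traj = {}
for g in genes:
    if g in m1:
        traj[g] = (ages, shared + 0.1 * rng.standard_normal(15))
    else:
        traj[g] = (ages, rng.standard_normal(15))
tc = cd.trajectory_coherence_test(m1, traj, n_resample=1000, seed=SEED)
print(f"trajectory coherence of the planted module: median r = "
      f"{tc['median_r']:.2f}, p = {tc['p']:.2g}")

# ---- annotation similarity network ----------------------------------------
families = {**annots, **{f"det_{k}": v for k, v in modules.items()}}
names = list(families)
P = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
for i, a in enumerate(names):
    for j, b in enumerate(names):
        if i < j:
            df = cd.fisher_enrichment({a: families[a]}, {b: families[b]}, genes)
            P.iloc[i, j] = P.iloc[j, i] = df.loc[0, "p"]
net = cd.annotation_graph(P, seed=SEED)
communities = net["communities"]
ncomm = len(set(communities.values()))
print(f"annotation network: {len(net['kept'])} sets kept, "
      f"{ncomm} Louvain communities "
      f"(planted and detected versions of a module co-cluster)")

(out / "summary.json").write_text(
    json.dumps(
        {
            "ppi": {"median_degree": ppi["median_degree"], "p": ppi["p"]},
            "trajectory": {"median_r": tc["median_r"], "p": tc["p"]},
            "communities": {k: int(v) for k, v in communities.items()},
        },
        indent=2,
    )
)
print("wrote results/enrichment/")
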