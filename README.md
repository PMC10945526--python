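# cortexdem

Dense gene-expression maps (DEMs) on cortical surface meshes, with the
spatial statistics that make them useful.

Bulk transcriptomic atlases of the human cortex sample expression at a few
hundred locations per donor, while surface-based neuroimaging works with
meshes of tens of thousands of vertices. `cortexdem` bridges the two: it
propagates sparse multi-donor gene × sample measurements into spatially
dense per-gene vertex maps, and implements the downstream analyses that such
maps enable — spin-permutation significance testing, transcriptional
distinctiveness peaks, expression-gradient orientation fields and border
discovery, folding-alignment tests, weighted co-expression modules, and
resampling-based gene-set enrichment. A synthetic-cortex generator with
planted ground truth makes every stage testable end to end without any
external download.

## The model

For donor $d$ and gene $g$, samples are mapped to their nearest cortical
vertices (samples > 20 mm from the surface are excluded), propagated to all
vertices by nearest-neighbor interpolation on the spherical projection,
smoothed with a geodesic Gaussian kernel (FWHM 20 mm,
$\sigma = \mathrm{FWHM}/(2\sqrt{2\ln 2})$), and z-scored across vertices:

$$z_{g}(v) = \frac{1}{D_g}\sum_{d=1}^{D_g} \frac{x_{gd}(v) - \mu_{gd}}{\sigma_{gd}}$$

Per-donor z-scoring removes affine donor effects exactly; Y-chromosome genes
average over male donors only. On these maps:

- **Transcriptional distinctiveness** $\mathrm{TD}(v) = \tfrac1G\sum_g |z_g(v)|$,
  with peaks calibrated by a max-statistic over independent per-gene spins of
  the sphere and subdivided by Gaussian-mixture clustering (k by BIC, 2–18).
- **Spin tests**: two maps are compared by Pearson/Spearman/Dice/ΔZ or
  angle-skewness statistics against a null built from uniform random
  rotations of one map's spherical projection,
  $p = (1 + \#\{\text{null} \geq \text{obs}\})/(1 + n_{\text{spin}})$.
- **Gradients**: per-vertex tangential gradients of every gene map;
  principal orientation by uncentered 2×2 second-moment eigenanalysis; genes
  ranked by mean gradient over boundary vertices against size-matched null
  gene sets.
- **Co-expression modules**: signed adjacency $a = ((1+r)/2)^\beta$ with
  $\beta$ the smallest power reaching scale-free fit $r^2 > 0.8$,
  topological overlap (TOM), average-linkage module cores (≥ 30 genes),
  eigenmaps (first PC across vertices), merging at eigenmap $r > 0.9$, and
  kME membership classification; modules enriched for
  non-cortically-expressed genes are dropped.
- **Enrichment**: one-sided Fisher/hypergeometric tests with Bonferroni- or
  Holm–Šidák-style control, degree-decile-matched PPI connectivity nulls,
  developmental trajectory coherence (GCV splines at 20 log-age points),
  and Louvain communities on annotation-overlap networks.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(6 donors × 250 samples, 570 genes on an icosphere cortex; outputs under
`results/`):

```bash
python analysis/01_simulate_cortex.py
python analysis/02_build_dems.py
python analysis/03_reproducibility.py
python analysis/04_distinctiveness.py
```

`02` prints, for the noisy six-donor study:

```
library: 570 genes x 2562 vertices
sampling: d = 22.4 mm (rho = 1.99e-03 /mm^2)
truth recovery (structured genes): median r = 0.968
truth recovery (noise genes):      median r = -0.003 (no consistent pattern, as planted)
```

i.e. maps of spatially structured genes recover the planted truth almost up
to the smoothing ceiling, while genes without cortical patterning recover
nothing — the contrast the reproducibility filter relies on. `03` then
splits the donors into disjoint subsets (10 unique triplet pairings),
measures between-subset map agreement, and extrapolates a learning curve
$r(n) = a - b\,n^{-c}$ (here predicting gene-level $r = 0.98$ at six
donors); `04` finds the planted transcriptionally distinctive regions as
its two strongest spin-calibrated TD peaks. `05`–`07` continue with
gradients/border genes, co-expression modules (planted modules recovered at
ARI 1.0), and enrichment.

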