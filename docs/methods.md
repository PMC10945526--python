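# Methods

This note records the modeling assumptions, parameter choices, and numerical
decisions behind `cortexdem`, and what the synthetic benchmarks do and do not
establish about behavior on real cortical data.

## Surface machinery

**Mesh model.** A cortex is a triangulated mesh with a one-to-one spherical
projection (the registration sphere), per-vertex barycentric areas, and a
boolean cortex mask playing the role of the medial wall. Synthetic cortices
are subdivided icospheres (V = 10·4^s + 2); radius 100 mm gives a total area
(~1.25·10^5 mm²) within a factor of ~1.5 of a human hemisphere, so kernel
widths in mm transfer meaningfully.

**Geodesics.** Distances are graph shortest paths over mesh edges augmented
with straight-line chords to each vertex's 2-ring. Pure edge paths
overestimate surface distance anisotropically by up to ~8%; the 2-ring
chords reduce the error to ~1–3% against great-circle arcs on icospheres.
This is an approximation, not exact polyhedral geodesics; it is accurate at
the scales the smoothing kernels and distance analyses use (≳ 20 mm) and
increasingly coarse below the mean edge length.

**Smoothing.** `smooth_map` implements a geodesic Gaussian kernel,
σ = FWHM/(2√(2 ln 2)), truncated at 3σ, with area-weighted, row-normalized
weights; masked vertices neither donate nor receive weight. Row
normalization preserves constants to machine precision but preserves the
area-weighted mean of a generic map only approximately (~0.1–1% on an
icosphere): a kernel cannot be simultaneously row- and column-stochastic on
an irregular mesh. A kernel narrower than the mesh edge length degenerates
to the identity; callers should keep FWHM ≳ 2 edge lengths.

**Gradients.** The tangential gradient at a vertex is the slope of a
weighted least-squares affine fit over the closed 1-ring, projected into the
vertex tangent plane (normal = area-weighted face normals; first tangent
axis = projection of global +x, falling back to +y). The fit is linear in
the data, so the operator is precomputed as two sparse matrices — gradients
of a whole gene library are two sparse mat-vecs per gene. The fit is exact
for affine fields on planar meshes; on icosphere-4 the direction error
against analytic spherical-harmonic gradients is < 5° at 95% of vertices.
Vertices with fewer than 3 unmasked neighbors return a zero vector and a
degeneracy flag.

## Synthetic cortices

The generator emulates the statistical structure of a sparse multi-donor
cortical expression study, not its biology:

- **Eigenpatterns** are Gaussian random fields: white vertex noise smoothed
  at a configurable FWHM, then divided by the per-vertex kernel norm. The
  normalization makes the fields stationary (rotation-exchangeable) on the
  sphere. This matters: without it the mesh imprints a fixed variance
  pattern (vertex degrees and areas vary) on every map, and spin-based nulls
  become anticonservative for reasons that have nothing to do with the
  statistics under test — measured TD-peak family-wise error was 0.23 at
  nominal 0.05 before the correction and 0.05 after. Real cortical maps are
  not exactly stationary either; the pipeline's answer to that is the
  spun+interpolated null, which rebuilds maps from rotated sample locations
  and therefore carries any mesh- or sampling-locked structure into the
  null.
- **Module genes** are loading·eigenpattern + √(1−loading²)·independent GRF,
  z-scored; the default loading 0.8 gives planted kME ≈ 0.8, comparable to a
  well-defined co-expression module. Focal distinctive regions are modules
  whose eigenpattern is a smoothed geodesic patch (default radius 30 mm)
  instead of a global field.
- **Border genes** are logistic steps σ(s/w) across a great circle, by
  default one circle shared by all border genes (an areal boundary marked by
  many genes) with per-gene widths drawn from 1–3 mm. Steps much wider than
  that are indistinguishable from the background fields' own gradients at
  mesh resolution — border discovery is a sharpness contrast, and the
  generator plants the sharp case the statistic is designed for.
- **Noise genes** model transcripts without cortical expression: their
  measured values are drawn fresh per donor, so no spatial pattern survives
  donor averaging and their split-half reproducibility is centered on zero.
  (Sampling them from a shared white-noise truth map would make them
  perfectly reproducible "patterns", which is the wrong null.)
- **Donor effects** are affine (scale 1±0.1, shift 0±0.5, measurement noise
  sd 0.3 on unit-variance truth) — exactly the nuisance class per-donor
  z-scoring removes; tests assert the invariance.
- **Folds** are sums of tangential plane waves (default wavelength 60 mm,
  resolved on icosphere-4) with the analytic orientation retained;
  "curvature" is the graph Laplacian of sulcal depth. **Parcellations** are
  spherical k-means labels with islands reassigned to the neighbor sharing
  the longest boundary.

Default study scale: 6 donors × 250 samples on an icosphere-4 (2562
vertices), inter-sample distance ≈ 22 mm, map smoothing FWHM 20 mm —
sampling density, kernel width, and mesh resolution in the same ratios as a
sparse donor atlas on a dense mesh. What passing benchmarks show is that the
*statistics* behave (calibration, recovery, invariances) under these
conditions; they cannot certify performance under real microarray noise,
probe effects, or registration error, which the generator deliberately does
not model.

## Statistical machinery

**Spin tests.** Nulls use uniform SO(3) rotations with nearest-vertex
reassignment (no barycentric interpolation, no mirroring — single
hemisphere). p-values use the (1+exceedances)/(1+n) convention, valid at any
finite spin count. Tangent fields are spun by rotating the 3-D vectors and
re-projecting into the target vertex's tangent plane — the natural parallel
transport of an axial direction; on developable patches this equals
comparing angles after flattening.

**Max-statistic thresholds** (TD peaks, high-gradient regions): per
permutation every gene's map is independently assigned a random ensemble
rotation, the vertex statistic is recomputed, and the map maximum recorded;
the threshold is the 95th percentile of maxima, controlling family-wise
error across vertices.

**TD peak clustering.** Suprathreshold vertices are represented by their
pairwise Spearman correlation of gene ranks, embedded by PCA at 95%
retained variance, and clustered with full-covariance Gaussian mixtures
(10 restarts, fixed seed), k chosen by BIC over 2–18 (ties to smaller k).
The GMM covariance floor is 10⁻³ of the mean embedding variance: with an
unregularized floor, BIC rewards degenerate near-zero-variance components
and splits genuinely homogeneous peaks. When the planted structure is
smooth and global rather than focal, BIC has no reason to stop small —
saturating the k range on such data is expected behavior, not failure.

**GLM with cluster-extent correction.** Vertex-wise OLS; suprathreshold
(p < α, two-sided) vertices grouped by edge-connectivity; the null of
maximum significant-cluster size comes from Freedman–Lane permutation
(residuals of the reduced model permuted), and observed clusters above the
null 95th percentile survive. Measured family-wise error is conservative
(~0.02 at nominal 0.05 over 200 null cohorts with spatially correlated
noise); power on a planted 30 mm patch at d = 1.5, n = 40 gives Dice ≈ 1.

**Learning curves.** r(n) = a − b·n^(−c) by bounded nonlinear least squares
(a ∈ [−1,1], b,c > 0); non-convergence falls back to a flagged flat fit.

**Distance decoupling / trajectory smoothing.** Smooth fits use SciPy's
GCV-penalized cubic smoothing spline (duplicate abscissae averaged first);
a cubic polynomial is the fallback when fewer than 10 distinct distances
exist. Parcel centroids are geodesic medoids.

**ISH boundary statistic.** The split maximizing |t| between column means
left and right of the candidate boundary, margins of 2 columns excluded,
ties to the lowest index. The pooled-variance t is the default: for a pure
intensity ramp the pooled statistic peaks at the central split, whereas
Welch's is constant across splits there (the mean difference and the
combined variance term are both split-invariant) and cannot localize; Welch
remains available via `equal_var=False`.

## Co-expression pipeline

Signed soft adjacency a = ((1+r)/2)^β, β the smallest power with signed
scale-free fit R² > 0.8 over 10 connectivity bins (best-fitting β with a
warning when none reaches it — smooth synthetic libraries often cannot,
since their correlation structure is low-rank rather than scale-free).
Unsigned TOM ω = (ΣₐA·A + a)/(min k + 1 − a). Module detection proceeds in
three stages: (1) *cores* from average-linkage clustering of 1−TOM with a
static cut at the lowest height maximizing the number of ≥ 30-gene
clusters — the height where every tight module has crystallized but
unstructured genes have not yet agglomerated; (2) eigenmap computation
(first PC across vertices, sign-oriented to positive mean member
correlation, z-scored) and iterative merging of module pairs with eigenmap
r > 0.9; (3) kME classification of every gene to its best module when
max |kME| ≥ 0.3, else unassigned. A single fixed-height cut was tried first
and proved fragile in exactly the two directions one would predict: cut low
it fragments modules, cut high it sweeps noise genes in; the
core-then-classify design recovers planted modules at ARI ≥ 0.99 both on
ideal libraries and on libraries rebuilt through the full
interpolate→smooth→average pipeline, where interpolation duplicates create
near-identical maps that defeat gap-based height rules. Modules enriched
for non-cortically-expressed genes (one-sided Fisher, α = 0.05/M) are
dropped after detection.

## Known limitations

- Graph geodesics and 1-ring gradients degrade below ~2 mesh edge lengths;
  all defaults keep analysis scales above that.
- The spin machinery assumes a meaningful spherical projection; strongly
  distorted registrations would need area-corrected variants that are not
  implemented.
- The scale-free soft-power criterion rarely triggers on low-rank synthetic
  correlation structure; the fallback (best-fitting β, flagged) is the
  normal path there, and β can always be fixed by hand.
- `fit_learning_curve` extrapolates a saturating form; it says nothing
  about regimes the observed sizes do not probe.
- Enrichment harmonizes gene identifiers by exact symbol match only.
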