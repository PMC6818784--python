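# Methods

This note documents the models and estimators implemented in `lipmorph`, the
numerical choices behind them, the synthetic study conditions used by the
test suite and the acceptance script, and the known limitations.

## Surface representation and preprocessing

Meshes are triangulated surfaces in millimetres (`TriMesh`), landmarks the
eight soft-tissue points of the lip region (subnasale `sn`, labiale superius
`ls`, labiale inferius `li`, crista philtri left/right `cphL`/`cphR`,
cheilion left/right `chL`/`chR`, pogonion `pg`), each bound to its nearest
mesh vertex (snap tolerance 2 mm by default).

*Smoothing* is a Taubin-style two-step Laplacian (uniform weights, equal
shrink/inflate factors λ = strength/2, boundary vertices pinned) followed by
a uniform rescale about the centroid that restores the signed-volume proxy;
the contract is < 1 % volume drift, not a particular scheme. Scan denoising
before feature extraction uses 25 iterations by default: enough to suppress
0.1 mm-scale sensor noise while leaving millimetre-scale anatomy intact.

*Pose* is canonicalised from three landmarks: origin at `sn`, `chL → chR`
along +x, the cheilion-midpoint → `sn` direction (orthogonalised) along +y.
A cylinder-based whole-face normalisation would need full-face coverage;
the three-landmark frame needs only the lip region and is rigid, so all
curvature and distance features are unaffected.

*Template regularisation* rigidly registers the template to the scan
(landmark-initialised ICP, rigid only, stopping when the mean nearest-point
distance improves by < 1e-6 mm or after 50 iterations) and replaces each
registered template vertex by the inverse-distance-weighted mean of its k
nearest scan vertices (k = 3 default). The output inherits the template's
face list, giving dense correspondence across a sample. The default
synthetic template is a noise-free mid-parameter lip patch with 110 × 65 =
7150 vertices.

## Geodesic paths

The `exact` engine computes a locally shortest geodesic polyline whose
points lie wherever the path crosses mesh edges:

1. initialise with the edge-graph Dijkstra route between the endpoint
   vertices (endpoints given as raw points or landmarks are projected onto
   the surface and kept exactly);
2. iterate two moves until the length improvement falls below 1e-12
   relative: (a) every run of edge crossings between anchor points is
   re-solved exactly by unfolding the crossed face strip into the plane and
   string-pulling (funnel algorithm) through the unfolded portals; (b) every
   interior vertex anchor whose one-sided unfolded wedge angle is below π is
   shortcut across the flatter wedge.

Both moves are accepted only when they strictly shorten the polyline and
preserve face-to-face connectivity, so the result is never longer than the
Dijkstra route, and on developable regions it is exact (the triangulated
plane reproduces straight lines to machine precision; icosphere antipodal
errors are 0.06 % at subdivision 4 and shrink with refinement). Ties between
equal-length routes resolve deterministically from the Dijkstra
initialisation. The method converges to a *local* geodesic; on strongly
non-convex regions a shorter homotopy class can exist, which is acceptable
for descriptor work because the initialisation is the globally shortest
edge route.

The `fast_marching` engine solves the eikonal equation with the standard
first-order two-point triangle update (obtuse configurations fall back to
the Dijkstra update) and traces the path by steepest descent on the vertex
distance field. It is cheaper on dense meshes but first-order accurate, and
its descent trace follows mesh edges; the package defaults to the exact
engine below 10,000 vertices.

The lower-lip-tone family shifts the (`chL`, `li`, `chR`) waypoints
downwards (−y in the canonical pose) by i·2 mm for i = 0…4, re-projects them
onto the surface, and traces the three-waypoint polyline for each offset.
The offset and path count are parameters (defaults 2 mm, 5).

## Curvature

Principal curvatures come from the normal-cycle tensor. Per vertex cell,
every incident edge e contributes half its length times β(e)·ē ēᵀ, where
β(e) is the signed dihedral angle across e (convex with respect to the
outward normal = positive) and ē the unit edge direction. Cell tensors are
then averaged, area-weighted, over a geodesic ball approximated by
edge-graph distances — this realises |e ∩ B| at the resolution of the vertex
cells. Of the three eigenvalues, the one whose eigenvector is closest to
the (area-weighted face-normal) estimate of the vertex normal is discarded;
the remaining two are k₁ ≥ k₂. The tensor's tangent eigenvectors swap the
principal directions (the eigenvector of k₁ points along the direction of
minimum normal curvature); directions are not exposed, so the swap is
internal.

The ball radius trades noise suppression against smearing of sharp detail.
The default is 2× the mean edge length, which suits noise-free geometry
(oracle errors: sphere ≤ 1.2 %, cylinder ≤ 0.1 %, saddle ≤ 2.6 % at the
fixture resolutions; all well within the 5 % oracle tolerance). For scanned
(noisy) surfaces the pipeline uses a physical radius of 2.5 mm instead,
because white vertex noise of amplitude σ produces curvature noise ~σ/h² at
mesh spacing h — refining the mesh amplifies it — whereas a fixed physical
ball averages it away.

Derived measures follow the standard definitions: M = (k₁+k₂)/2, Ga = k₁k₂,
Sh = ½ − (1/π)·arctan[(k₁+k₂)/(k₁−k₂)] mapped to [0, 1] (0 = convex cap,
¼ = ridge, ½ = saddle/flat, ¾ = rut, 1 = concave cup), and curvedness
C = √((k₁²+k₂²)/2). At umbilic points the shape index takes its one-sided
limits: 0 if k₁ = k₂ > 0, 1 if < 0, ½ if both vanish. An alternative
curvedness reading ((k₁²+k₂²))² is available behind
`derived_measures(..., curvedness="literal")` for comparison; the two agree
on the unit sphere. Vertices whose ball touches an open boundary are flagged
and excluded from descriptor sampling by default.

## Descriptors

A path's curvature samples are the field values at the nearest mesh vertex
of each path point, with consecutive duplicates removed (this realises "path
nodes" for paths that cross edges between vertices). Each of M, Ga, C, Sh is
histogram-normalised into b equal-width bins spanning the sampled min–max
range (rightmost edge inclusive; a constant sample puts all mass in bin 1),
so every 4b-block is a set of four unit-sum histograms. b must not exceed
the minimum sample count over all paths in the dataset; the legal values are
5, 10, 15, 20, 25. The per-path range makes blocks scale-free; a global
fixed range per measure can be supplied for cross-sample comparability of
absolute curvature levels.

Distance features use the on-surface path endpoints: ED is the straight-line
distance between them (which makes GD ≥ ED an exact identity) and GD the
geodesic polyline length. `combine_and_scale` min-max scales each column to
[0, 1] over the sample (constant columns → 0), ordering blocks GC, GD, ED.
GD/ED columns are scaled per column, like every other column.

## Classification

Gentle boosting fits, per class (one-vs-all), an additive ensemble of
depth-1 regression stumps: each round minimises the weighted least-squares
error of the ±1 class indicator, adds the stump response to the class score
and reweights w ← w·exp(−y·f). The round count defaults to 100. Prediction
is the argmax of class scores; AUC is macro-averaged one-vs-rest on those
scores. Because stump ensembles are piecewise constant, distinct test points
can tie in score, which can cost a sliver of AUC even on perfectly separated
data. The SVM baseline wraps a scikit-learn SVC (RBF or linear, one-vs-rest
decision values). Cross-validation is stratified k-fold (default 5) with an
explicit seed; reports are bit-reproducible for a fixed seed. One-way ANOVA
(F = MS_between/MS_within on (g−1, N−g) degrees of freedom) compares per-run
accuracies across feature sets.

## Categorisation

k-means uses the k-means++ initialisation (first centroid uniform over the
points; each next drawn with probability proportional to the *squared*
distance to the nearest chosen centroid — plain-distance weighting is
available behind `squared=False`), Lloyd iterations until the assignment is
stable (SSE is asserted non-increasing every iteration), emptied clusters
re-seeded from the farthest point, and 100 restarts with the minimum-SSE
model kept. Distances are Euclidean throughout.

Validity indices: silhouette (per-point mean of s(i) = (b−a)/max(a,b), with
a(i) the mean intra-cluster distance excluding self — singletons contribute
s = 0 — and b(i) the smallest mean distance to another cluster); Dunn
(minimum pairwise inter-cluster distance over maximum within-cluster
diameter); Calinski–Harabasz (trace(S_B)/trace(S_W) · (n−k)/(k−1); the
degrees-of-freedom factor is also available in an (n−1)/(n−k) variant for
comparison, as printed sources disagree). `select_k` sweeps K = 2…9, 50
times by default, fits with full restarts each time, and tabulates the
percentage of repeats in which each index's argmax lands on each K.

## Category effects on shape (PLSR)

Categories are dummy-encoded into C−1 indicator columns (reference = first
category in sorted order; changing the reference changes individual dummies
but not the multiple effect). Partial least squares regresses the n × 3V
shape matrix (rows = concatenated x,y,z of template-registered vertices) on
the dummies, with the component count defaulting to min(C−1, 10, n−1) — at
that rank the fit coincides with least squares, which keeps the nested-model
identities exact. Per vertex and dummy the effect magnitude is the Euclidean
norm of the 3-D coefficient (mm per unit dummy); partial R² is
(SSE_reduced − SSE_full)/SSE_reduced with the other dummies retained in the
reduced model; the multiple effect refits the full dummy block against the
intercept-only model (so multiple R² ≥ every partial R²). Significance is a
permutation test of the per-vertex R² statistic: rows of the dummy matrix
are permuted jointly, and the one-sided add-one estimate
p = (1 + #{permuted ≥ observed})/(n_perm + 1) is reported (minimum
attainable p = 1/(n_perm+1); default 1000 permutations). One permutation
sequence is shared across vertices, so p-values are correlated *across*
vertices — efficient and exact per vertex, but uniformity tests over the
vertex field reject slightly more often than their nominal level. Heat maps
export magnitude and R² with a continuous colour ramp, and significance as
the two-colour map (yellow strictly below 0.001, green otherwise), as PLY
vertex quality plus RGB.

## Synthetic study conditions

The generator emulates landmark-annotated lip-region scans as smooth
80 × 60 mm height-field patches (100 × 75 vertices, ~0.8 mm spacing, open
boundary): a gentle dome plus windowed relief — a philtrum groove/ridge
between `ls` and `sn`, a Cupid's-bow ridge above `ls`, a lower-lip bulge
below `li` — with every relief term multiplied by a smoothstep mask that
vanishes within 1.5 mm of every landmark (1 beyond 3 mm). The mask is what
makes "no category signal in the landmarks" hold on a *discretised* surface:
without it, the tilted facets next to a landmark shift its surface
projection by category. Landmarks are placed analytically and bound to the
generated mesh.

Per-mesh variation has three parts: white vertex noise (σ = 0.08 mm, typical
of laser-scan residuals), optional landmark jitter (default 0), and a
low-frequency "individual variation" field (random long-wavelength cosine
modes, RMS 1 mm, wavelengths ≥ 30 mm) standing in for between-subject
facial variability. The default philtrum categories span the clinical
spectrum — deep groove (+3.5 mm), shallow groove (+0.8 mm), convex/prominent
philtrum (−3.5 mm) at a common 4.5 mm width — chosen so the categories are
cleanly separated in curvature while their geodesic arc lengths (which grow
with depth² regardless of sign) overlap heavily, and inter-landmark
distances carry no signal at all. Cohorts default to 3 categories × 30
meshes.

What passing tests on this cohort do show: the full pipeline (smoothing,
pose, geodesics, curvature, histogram descriptors, scaling, boosting,
clustering) recovers categories whose signature lives purely in surface
bending, at realistic noise, and that distance features alone cannot. What
they do not show: performance on real scans with acquisition artefacts
(holes, spikes, occlusion), true anatomical shape distributions, manual
landmarking error structure, or categories defined by global size — the
generator's variation is parametric and its relief analytic.

## Problem sizes

The test suite and the acceptance script run at desk scale on one CPU:
curvature oracles at 2.5–10 k vertices, geodesic oracles at ≤ 10 k vertices,
the feature-ordering experiment on 90 meshes of ~7.5 k vertices each, the
K-selection sweep at n = 60 with the full 50 × (2…9) × 100-restart protocol,
and the PLSR injection at n = 100 meshes × 800 vertices with 1000
permutations. These sizes keep a full run in minutes while leaving every
protocol parameter (folds, restarts, repeats, permutation count, offsets) at
its study value.

## Known limitations

- The exact geodesic is locally, not provably globally, shortest; see above.
- Fast-marching path tracing follows mesh edges (the distance field is
  first-order accurate, the trace cruder); use the exact engine when the
  path geometry itself matters.
- Normal-cycle curvature at open-boundary vertices is computed from the
  truncated neighbourhood and flagged rather than corrected.
- Histogram descriptors at b = 5 on short paths (≈ 10–20 samples) are
  coarse; the philtrum's shortest paths cap the legal b at 5 for the default
  synthetic cohort.
- `CategoryShapeModel` assumes meshes already share vertex correspondence
  (template-regularised); it does not register them.
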