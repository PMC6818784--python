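# lipmorph

Automatic classification and categorisation of morphological lip traits on 3D
facial surface meshes.

Clinicians describe lip morphology — philtrum shape, Cupid's bow, the upper
and lower vermilion contours, the lip–chin profile, lower lip tone — by eye,
which is slow and subjective. `lipmorph` implements an automatic pipeline for
these traits on triangulated facial scans with anthropometric landmarks:

1. **Geodesic paths.** Shortest on-surface paths are traced between the eight
   soft-tissue landmarks of the lip region (`sn, ls, li, cphL, cphR, chL,
   chR, pg`), one fixed path list per trait (five paths for the philtrum, two
   for Cupid's bow, …; the lower lip tone uses five paths offset vertically
   by 2 mm). The exact engine initialises with edge-graph Dijkstra and
   shortens to a locally shortest geodesic by unfolding the crossed face
   strips into the plane (string pulling) plus vertex-wedge shortcuts; a
   first-order fast-marching engine is available for dense meshes.
2. **Curvature descriptors.** Per-vertex principal curvatures k₁ ≥ k₂ come
   from the normal-cycle tensor T(v) = (1/|B|) Σₑ β(e)·|e∩B|·ē ēᵀ accumulated
   over a geodesic ball B; from them the mean curvature M = (k₁+k₂)/2,
   Gaussian curvature Ga = k₁k₂, shape index
   Sh = ½ − (1/π)·arctan[(k₁+k₂)/(k₁−k₂)] ∈ [0,1] and curvedness
   C = √((k₁²+k₂²)/2). Each measure is sampled at the mesh vertices along a
   path and histogram-normalised into b ∈ {5,10,15,20,25} relative
   frequencies, giving a 4b-element block per path (ordered [M, Ga, C, Sh]);
   a trait's blocks concatenate into its geodesic-curvature (GC) descriptor,
   optionally joined by geodesic (GD) and Euclidean (ED) inter-landmark
   distances and min-max scaled to [0,1] per column.
3. **Classification.** Multiclass gentle boosting (one-vs-all regression
   stumps, robust to class imbalance) and a multiclass SVM, evaluated by
   stratified 5-fold cross-validation (accuracy % and macro one-vs-rest AUC),
   with one-way ANOVA to compare feature sets across runs.
4. **Categorisation.** k-means++ with 100 restarts (minimum-SSE model kept);
   the cluster count K is selected by sweeping K = 2…9 fifty times and
   scoring silhouette, Dunn and Calinski–Harabasz indices.
5. **Visualisation.** Trait categories are dummy-encoded (C−1 indicators)
   and regressed against the dense vertex coordinates of
   template-regularised meshes by partial least squares; per-vertex effect
   magnitudes, partial R² and 1000-permutation p-values are exported as PLY
   heat maps (yellow p < 0.001 / green otherwise).

Because clinical facial scans are access-restricted, the package ships a
first-class synthetic generator: analytic oracle surfaces (plane, sphere,
cylinder, saddle, with closed-form curvatures) and parametric lip patches
whose category-dependent relief (groove depth/width, bow amplitude, bulge
height) is windowed to vanish near every landmark, so inter-landmark
distances carry no category signal by construction.

## Worked example

```python
import numpy as np
import lipmorph as lm
from lipmorph.pipeline import cohort_descriptors, feature_ordering_experiment

config = lm.SyntheticConfig(seed=0)          # 3 categories x 30 lip patches
descriptors, labels = cohort_descriptors(config, b=5)
reports = feature_ordering_experiment(config, b=5, seed=0,
                                      descriptors=descriptors, labels=labels)
for name, report in reports.items():
    print(f"{name:>6}: accuracy {report.mean_accuracy:5.1f}%  "
          f"AUC {report.mean_auc:.3f}")
```

prints

```
 GC+GD: accuracy  98.9%  AUC 0.994
    GD: accuracy  75.6%  AUC 0.900
    ED: accuracy  26.7%  AUC 0.409
```

The geodesic-curvature descriptor combined with geodesic distances (GC+GD)
classifies the three philtrum categories essentially perfectly; geodesic
distances alone (GD) retain partial signal because a deeper groove lengthens
the on-surface paths; plain landmark distances (ED) sit at the 33% chance
level, as the generator guarantees by construction. The same descriptors
cluster back into the true categories without labels:

```python
X = lm.combine_and_scale(descriptors, ("GC", "GD"))
model = lm.kmeans_fit(X, 3, rng=0, restarts=100)      # ARI vs truth = 1.0
sweep = lm.select_k(X, kmin=2, kmax=9, repeats=50, rng=0)
print(sweep.best_k("SI"))                              # -> 3
```

A command-line interface mirrors the library:

```bash
lipmorph simulate --trait philtrum --categories 3 --n 20 --seed 0 --out-dir cohort/
lipmorph classify --features feats.csv --labels labels.csv --classifier boost --out report.json
lipmorph cluster  --features feats.csv --kmin 2 --kmax 9 --repeats 50 --out sweep.json
lipmorph visualize --shapes shapes.csv --labels labels.csv --faces template.ply --out-prefix effect_
```

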