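# Methods

## Model and procedure

The package operates on point patterns: each detected cell is a node
v = (x_v, y_v) with a phenotype in {T, B}. Coordinates are pixels in the
WSI frame (origin top-left, y down); the scan resolution (default
0.253 μm/px) converts to micrometres only at reporting boundaries, so all
geometry is computed once, in one unit.

**Filtered Delaunay graphs.** The Delaunay triangulation is computed over
all cells regardless of phenotype (`scipy.spatial.Delaunay`). A triangle
whose circumcircle radius R is smaller than the cutoff t contributes all
three of its sides as edges. Two rules are deliberate:

* *Union rule* — an edge survives if **any** incident triangle qualifies.
  Boundary edges have a single incident triangle; interior edges have two,
  and the smaller of the two circumradii decides. This follows from reading
  "every side of a qualifying triangle is an edge" as a union over
  triangles.
* *Strict inequality* — R < t, not ≤. Immaterial for generic point sets,
  visible on exact regular grids (a spacing-s grid connects for
  t > s/√2, not at equality), and the calibration tests rely on it.

Collinear triangles get R = +∞ and never qualify; "collinear" means the
triangle's area is below 1e-12 of its squared longest side, a scale-free
tolerance. Exact duplicate coordinates would make the triangulation
ambiguous, so at load time only the record with the lexicographically
smallest cell id is kept per coordinate (warning logged).

Connected components with at least `min_nodes` cells (default 10 — roughly
the smallest aggregate a pathologist would outline; no published minimum
exists) become infiltrates. t defaults to 45 px at 0.253 μm/px; under a
different resolution the default preserves the physical cutoff
45 · 0.253 = 11.385 μm, since the biology (direct cell contact) is a
physical length, not a pixel count.

**Edge labels and κ.** Same-phenotype edges are α; an inter-type edge is
γᵢ where i is the number of A–A edges at its endpoint of designated type A
(A = B cells throughout the defaults). With exactly two phenotypes every
inter-type edge has exactly one A endpoint, so the label is well defined;
inputs with a third phenotype are rejected rather than guessed. Then

κ(a) = (|E| − |Eα| − Σ_{j≤a} |Eγⱼ|) / (|E| − |Eα|),

equivalently the fraction of inter-type edges whose A endpoint has more
than a A–A links. A graph with no inter-type edges has no T/B interface to
score; κ is defined as 0 there (the feature-vector code flags the case).
κ(a) is non-increasing in a and vanishes once a reaches the largest
observed γ index — both property-tested.

**Other features.** Homogeneity H = |Eα|/|E| (undefined and refused on an
edgeless graph — excluded upstream by `min_nodes`). The clustering
coefficient is the mean of local coefficients with the 1/|V| prefactor
taken literally: isolated and degree-1 nodes contribute 0 to the sum but
stay in the denominator. Degree statistics are P(k) = n_k/|V| and
⟨K⟩ = 2|E|/|V|. The mean pairwise Euclidean distance is exact (scipy
`pdist`) up to 5,000 nodes; above that a seeded sample of 10⁶ ordered pairs
is used and the result is flagged as subsampled (sampling error ≈ 0.1% at
that size). Degrees on Delaunay subgraphs are approximately Poisson; the
package reports P(k) and asserts nothing about its shape.

**Compartments and hulls.** Removing all inter-type edges and taking
connected components restricted to one phenotype yields compartments;
single cells and pairs do not span a compartment (minimum 3 nodes).
Concave outlines are alpha-shape boundaries: the union of the infiltrate's
own filtered triangles, so hull and graph are mutually consistent by
construction; the default alpha equals t. For a hand-supplied point set the
same construction runs on a fresh triangulation; fewer than 3 points, or no
qualifying triangle, yields no hull.

**Cutoff calibration.** Each annotation polygon (GeoJSON, pixel frame,
boundary-inclusive point-in-polygon) is scored at each candidate t by the
number of connected components of the t-filtered graph induced on the
enclosed cells — edges to outside cells are ignored, because connectivity
is being judged *inside* the annotated cluster. The chosen t is the
smallest grid value whose non-fragmentation fraction reaches
`target_fraction` (default 1.0); if no grid value reaches it, the smallest
maximizer is returned flagged `best_approximation`. The fraction is
non-decreasing in t (edge sets grow monotonically), which the report
asserts. Kept/removed Delaunay edge-length medians at the chosen t are
reported in μm; kept edges come from small circumcircles, so their median
is below the removed median whenever both exist. The default grid is
5–100 px in steps of 5. Per-edge "birth radii" (smallest incident
circumradius) are precomputed once per ROI, so the sweep costs one
triangulation regardless of grid size.

**Classification.** The SVM uses five features: |E|, |Eα^B|/|E|,
|V_B|/|V|, κ(2), κ(5). Choices the classification layer had to fix itself
(no published defaults exist for them):

* radial kernel with C = 1 and kernel width 1/(p · Var(X_train)) — the
  `gamma="scale"` convention;
* z-score standardization fitted on the training folds of each split only
  (the features span orders of magnitude: |E| in the hundreds, κ in
  [0, 1]); leakage is guarded by a test that plants an extreme outlier in a
  test fold and checks the fold's other predictions are unchanged;
* stratified 5-fold splits with a caller-supplied seed;
* one-vs-one voting for the multiclass prediction; per-class metrics are
  one-vs-rest confusions on each test fold.

Metrics are means of per-fold ratios (not ratios of pooled counts), and the
overall row is the unweighted macro-average of the four per-class values —
the convention that reproduces a published overall row from its per-class
rows. Any ratio with a zero denominator is reported as undefined, never
silently 0, and undefined fold values are skipped in averaging. Besides the
macro metrics, the plain multiclass accuracy (fraction of correct test
predictions, averaged over folds) is reported: its chance level on a
balanced 4-class problem is 0.25, which the permutation check uses.

Class comparisons use Kruskal–Wallis across all classes and Mann–Whitney U
of each class against the pooled rest, per feature, with raw p-values at a
0.001 level and no multiplicity correction (the level is strict enough that
correction would not change conclusions on the intended sample sizes).
PCA runs on z-scored features over a ten-feature set; constant features are
dropped with a warning since their z-score is undefined.

## Synthetic patterns

The generator emulates the four classes' phenomenology, not any particular
dataset:

| class | B fraction | geometry |
|---|---|---|
| T_CELL_AREA | 0.17 | uniform disc, labels shuffled |
| MIXED_UNSTRUCTURED | 0.35 | uniform disc, labels shuffled |
| INTERMEDIATE | 0.60 | 75% of B cells in 3 Gaussian clumps (σ = 1.5 spacings) over a T background |
| TLO_LIKE | 0.50 | dense B core disc with 5% interspersed T, T-cell mantle sized for equal density |

B fractions follow the reported tendencies for the classes (T-cell areas
around 17 B per 100 cells, intermediately organized around 60–70); the
clump count, clump width and clumped share are the package's own choices of
what "some B-cell connections without compartments" looks like.

Placement is a hard-core (dart-throwing) process with minimum separation
0.8 × spacing: nuclei physically exclude each other, and a pure Poisson
pattern at the same intensity is visibly too irregular — its longest
Delaunay edges would fragment an infiltrate at the default cutoff, which
real contact-level infiltrates do not. The disc radius 1.3·s·√(n/π) makes
the mean nearest-neighbour distance ≈ s (default 8 μm, below the ~11 μm
cutoff, so each simulated infiltrate is a single component at the default
t). Cohorts derive per-pattern seeds from one master seed via a
`SeedSequence`, making every pattern reproducible and independent.

What the generator does **not** model: detection noise (missed or
hallucinated cells, phenotype errors), staining artifacts, tissue
anisotropy, vessels and ducts carving holes in infiltrates, and the
continuum between classes that makes real intermediately organized
structures hard even for pathologists. Synthetic classes are cleanly
separated by construction, so a near-perfect cross-validated accuracy on
them demonstrates that the features carry the intended geometric signal
and the pipeline is wired correctly — not that comparable accuracy is
attainable on clinical material, where published per-class sensitivities
for intermediate structures are low.

## Problem sizes

Defaults used in tests and in `scripts/acceptance.py`: 200 cells per
pattern, 50 patterns per class for the SVM cohort, 20 seeds per class for
feature means, 20 label permutations for the null, and 100 random point
sets (n ≤ 200) for oracle-equivalence checks. These sizes give stable
statistics (the permutation-null accuracy varies by ~±0.02 across master
seeds) while keeping the whole suite in the tens of seconds.

## Known limitations

* Exactly two phenotypes. The γ label relies on every inter-type edge
  having a unique A endpoint; multi-phenotype inputs are rejected.
* The min-nodes floor (10) and the density-map ROI parameters are
  pragmatic defaults, not calibrated quantities.
* `fragmentation_at` treats every enclosed cell as part of the annotated
  infiltrate; stray cells inside an outline can keep an otherwise connected
  annotation fragmented at small t (by design: that is what "smallest t
  that does not fragment" protects against).
* Feature values near the decision boundary between INTERMEDIATE and
  TLO_LIKE overlap even in simulation when clumps merge; the SVM's
  performance on those two classes is the first thing to degrade as
  spacing or clump parameters are perturbed.
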