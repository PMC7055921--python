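# tlograph

Graph-based detection and classification of lymphocytic infiltrates — in
particular tertiary lymphoid organs/structures (TLOs) — from single-cell
coordinates in whole-slide images (WSIs).

TLOs are organized ectopic lymphoid aggregates with a B-cell core wrapped in
a T-cell zone, arising at sites of chronic inflammation (transplant
rejection, tumors, chronic lung infection). Distinguishing them from
ordinary immune infiltrates in CD3/CD20-stained slides is slow and
observer-dependent when done by eye. `tlograph` provides a reproducible,
quantitative alternative for anyone who already has per-cell coordinates and
T/B phenotypes from an upstream nucleus detector: computational pathologists,
immunologists, and translational researchers scoring inflammation.

## Method

Given the cell centres of one ROI or WSI:

1. **Neighborhood graphs.** A Delaunay triangulation is computed over all
   cell coordinates, phenotype-blind. Every side of a triangle whose
   circumcircle radius is smaller than a cutoff *t* becomes a graph edge
   (default *t* = 45 px at 0.253 μm/px ≈ 11 μm between cell centres).
   Connected components of the filtered graph are the infiltrates.
2. **Edge labels and features.** An edge is labelled *α* when its endpoints
   share a phenotype. Each remaining T–B edge is labelled *γᵢ*, where *i* is
   the number of B–B edges at its B endpoint. Per infiltrate the package
   computes |V|, |V_B|/|V|, |E|, |E_α|, |E_α^B|/|E|, homogeneity
   H = |E_α|/|E|, the global clustering coefficient C, the degree
   distribution P(k), the average degree ⟨K⟩ = 2|E|/|V|, the mean pairwise
   Euclidean distance, and the TLO-organization score

   κ(a) = (|E| − |E_α| − Σ_{j=0..a} |E_γj|) / (|E| − |E_α|),

   the fraction of T–B edges attached to a B cell with more than *a* B–B
   links. κ is high exactly when B cells form compact zones bordered by
   T cells — the TLO geometry — and, unlike H or C, it does not penalize the
   scattered T cells normally found inside a B-cell core.
3. **Cutoff calibration.** Given pathologist-drawn infiltrate outlines, the
   cutoff is chosen as the smallest candidate *t* for which the graph inside
   each outline is a single connected component.
4. **Classification.** A radial-kernel SVM over {|E|, |E_α^B|/|E|,
   |V_B|/|V|, κ(2), κ(5)} assigns each infiltrate to one of four
   organization classes — T-cell area, mixed unstructured, intermediately
   organized, TLO-like — under stratified 5-fold cross-validation, with
   per-class TPR/TNR/PPV/NPV/ACC/F1 and a macro-averaged overall row.
   PCA and Kruskal–Wallis / Mann–Whitney U tests characterize class
   separation feature by feature.

A synthetic-pattern module simulates all four classes at realistic cell
spacing (hard-core point patterns, ~8 μm mean nearest-neighbour distance),
so the full pipeline is testable without clinical material.

## Worked example

The κ score on a small labelled graph (a B-cell cluster around a hub, two
stray B cells, and 20 T cells each linked to one B cell):

```python
import tlograph as tg
from tlograph.examples import worked_example_graph

s = tg.label_edges(worked_example_graph(), "B")
print(f"|E| = {s.n_edges}, |E_alpha| = {s.n_alpha}, gamma counts = {s.gamma_counts}")
print(f"kappa(2) = {tg.kappa(s, 2):.2f}, kappa(5) = {tg.kappa(s, 5):.2f}")
```

```
|E| = 32, |E_alpha| = 12, gamma counts = {6: 1, 4: 3, 3: 4, 2: 6, 0: 6}
kappa(2) = 0.40, kappa(5) = 0.05
```

Of the 20 inter-type edges, 8 attach to B cells with more than two B–B
links (κ(2) = 8/20 = 0.40) and one to the 6-connected hub (κ(5) = 1/20).

The full pipeline on a simulated TLO-like infiltrate:

```python
spec = tg.SyntheticPatternSpec(class_label=tg.ClassLabel.TLO_LIKE, seed=3)
cm = tg.generate_pattern(spec)
(inf,) = tg.build_neighborhood_graphs(cm)
fv = tg.compute_feature_vector(inf, resolution_um_per_px=cm.resolution_um_per_px)
print(f"|V|={fv.n_nodes}  |E|={fv.n_edges}  frac_B={fv.frac_a:.2f}  "
      f"H={fv.homogeneity:.3f}  kappa(2)={fv.kappa[2]:.3f}  <K>={fv.avg_degree:.2f}")
```

```
|V|=200  |E|=554  frac_B=0.50  H=0.809  kappa(2)=0.981  <K>=5.54
```

κ(2) near 1 says nearly every T–B edge touches the organized B core; the
same pattern generated as a well-mixed infiltrate scores κ(2) ≈ 0.2.

The same workflow is available from the shell:

```sh
tlograph simulate --n-per-class 5 --seed 1 --out-dir cohort/
tlograph features --cells cohort/ --out features.csv
tlograph classify --features features.csv --labels cohort/labels.csv \
    --out metrics.json --seed 1
tlograph hulls --cells cohort/ --out hulls.geojson --compartments
```

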