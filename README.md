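# surfage

Surface-based analysis of cortical-thickness aging: how smoothing and
parcellation choices trade **association** strength against **prediction**
accuracy.

Neuroimaging aging studies do two different things with the same data:
association studies correlate a measure (here, cortical thickness per surface
vertex) with age region by region, while brain-age studies predict each
subject's age from the whole map and interpret the residual ("delta age") as a
biomarker. Both are run after preprocessing choices — a surface smoothing
kernel (FWHM 0–40 mm) and a parcellation level (vertexwise down to ~100
regions) — and these choices push the two analyses in *opposite* directions:
averaging reduces inter-individual variability, which raises regional
correlations with age but removes exactly the individual differences a
prediction model needs. `surfage` implements the full comparison pipeline and
exercises it end-to-end on synthetic cortical cohorts with known ground
truth.

## What it computes

For a cohort of thickness maps T (subjects × vertices) with ages Y on a
triangulated surface, over a grid of smoothing × parcellation conditions:

- **Heat-kernel smoothing** at a requested FWHM, as iterated one-ring
  diffusion steps whose squared widths add (n steps of width f/√n).
- **Parcel averaging** and projection back to the surface; summaries over 7
  macro regions.
- **Association maps**: per-unit Pearson r of thickness with age,
  t = r·√((n−2)/(1−r²)), two-sided p with Bonferroni control at α/m; and
  variability maps μ, σ, CV = σ/μ.
- **Resels**: the residuals of the per-vertex fit T(v) ~ 1 + Y, normalized to
  unit sum of squares, induce a metric on the mesh (edge length² =
  Σ_subjects Δresid²). Triangle areas in that metric sum to the 2D
  Lipschitz–Killing curvature; resels = LKC₂/(4 ln 2) and
  **effective FWHM** = √(area / resels) — one smoothness number per
  condition, comparable across smoothing and parcellation.
- **Brain age**: ordinary least squares of age on the first k principal
  components of the thickness features, k = 1…100, under repeated 10-fold
  cross-validation (RMSE, MAE, corr); in-sample adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1) and the **overfitting bias** adj R² − cv r².
- **Delta age**: δ₁ = Xβ₁ − Y (predicted − chronological) and
  δ₂ = δ₁ − Yβ₂, the residual of δ₁ on age — exactly mean-zero and
  age-orthogonal — plus cross-condition correlation matrices of δ₂.

The synthetic-cohort generator places spatially localized latent thinning
components on an icosphere with subject heterogeneity and vertex noise, so
all of the above can be validated against known slopes and applied kernel
widths.

## Worked example

```python
from surfage.grid import (default_scenario, run_grid,
                          association_vs_prediction, ConditionGrid)

mesh, cohort, truth = default_scenario(seed=1)      # 300 subjects, 2562 vertices
result = run_grid(mesh, cohort, ConditionGrid(seed=1))  # 6 FWHM x 3 resolutions
row = result.table.query("fwhm == 0 and parcellation == 0").iloc[0]
print(f"vertexwise, FWHM 0 mm: median r2 = {row.median_r2:.4f}, "
      f"resels = {row.resels2:.0f}, best RMSE = {row.best_rmse:.2f} y (k = {row.best_k})")
row = result.table.query("fwhm == 40 and parcellation == 100").iloc[0]
print(f"100 parcels, FWHM 40 mm: median r2 = {row.median_r2:.4f}, "
      f"resels = {row.resels2:.1f}, best RMSE = {row.best_rmse:.2f} y (k = {row.best_k})")
for name, s in association_vs_prediction(result.table).items():
    print(f"{name}: Spearman rho = {s['spearman_rho']:+.3f}")
```

prints (about 30 s on one CPU):

```
vertexwise, FWHM 0 mm: median r2 = 0.0120, resels = 1203, best RMSE = 9.52 y (k = 13)
100 parcels, FWHM 40 mm: median r2 = 0.1445, resels = 0.5, best RMSE = 9.91 y (k = 45)
median_r2_vs_resels2: Spearman rho = -0.969
adj_r2_vs_resels2: Spearman rho = +0.622
cv_r2_vs_median_r2: Spearman rho = -0.513
```

Reading: heavy averaging (40 mm kernel, 100 parcels) raises the median
age-association r² twelvefold while collapsing ~1200 resolution elements to
less than one and *worsening* cross-validated age prediction — the
association-vs-prediction inversion. The three rank correlations summarize it
across all 18 conditions: association strength falls with resel count,
variance of age explained by the features rises with resel count, and
prediction accuracy falls where regional association is strongest.

A CLI mirrors the library (`surfage simulate | smooth | parcellate |
associate | resels | predict | delta | grid | compare`); all tabular I/O is
headered delimited text and each grid run writes a JSON manifest with seeds
and timings.

## Layout

- `surfage.mesh` — surface data model, OBJ/GIFTI I/O, edges/areas/validation
- `surfage.synthetic` — icospheres, geodesic Voronoi parcellations, cohort
  generator with ground truth
- `surfage.smoothing` — diffusion smoothing at a requested FWHM
- `surfage.parcellation` — parcel averaging / projection / macro regions
- `surfage.association` — r/r²/t/p maps, CV maps, normalized residual fields
- `surfage.resels` — edge resls, triangle LKC, resel counts, effective FWHM
- `surfage.brainage` — PCA scores, cross-validated prediction, adjusted R²,
  δ₁/δ₂
- `surfage.grid` — condition grid orchestration and comparison summaries
- `surfage.cli` — command-line interface

See `docs/methods.md` for the model, estimators, parameter choices and
limitations.
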