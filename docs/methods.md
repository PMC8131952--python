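# Methods

## The analysis problem

Given per-vertex cortical thickness for a cross-sectional adult cohort, two
standard analyses are run under every combination of a surface smoothing
kernel (FWHM 0, 5, 10, 20, 30, 40 mm) and a spatial resolution (vertexwise,
or thickness averaged within parcels):

1. **Association**: per unit (vertex or parcel), the Pearson correlation of
   thickness with chronological age, summarized by the median r² over units.
2. **Prediction**: age regressed on the first k principal components of the
   thickness features under repeated 10-fold cross-validation, summarized by
   RMSE/MAE/corr per k, the in-sample adjusted R², and the per-subject delta
   ages δ₁ (predicted − chronological) and δ₂ (δ₁ orthogonalized against
   age).

The two are put on a common footing by the **resel count** of each
condition's statistical map, so the package can quantify how processing
choices move association and prediction in opposite directions.

## Synthetic cohort model

Real lifespan cohorts of this kind are access-controlled, so the package
ships a generator whose structure mirrors what the analysis assumes. For
subject i, vertex v:

    T_i(v) = μ(v) + Σ_k p_k(v) · (β_k z_i + η_ik) + γ_i + ε_iv

- `μ(v)`: a smooth baseline (low-order functions of position, rescaled to
  stay within 1.5–4.5 mm, filling the central 60% of that range).
- `p_k(v)`: K = 12 geodesic Gaussian bumps, FWHM = 6× the mean edge length
  (~13.5 mm on the default mesh), centred at farthest-point-sampled
  vertices. Geodesics are graph shortest paths over edge lengths — adequate
  on quasi-regular icospheres and deterministic.
- `z_i`: age standardized by the *specified* range midpoint and half-range
  (not the sample), so ground-truth slopes are sample-independent. Ages are
  uniform on [18, 88] years (n = 300 by default; the uniform lifespan design
  makes prediction deliberately harder than a Gaussian age distribution
  would).
- `β_k`: component loadings, stored as peak age slopes in mm/year. Default
  magnitudes uniform in [0.008, 0.02] mm/year, **all negative**:
  adult-lifespan cortical thinning is essentially universal with regionally
  varying rates, and the shared sign reproduces the empirical fact that the
  leading principal component of thickness is strongly age-related. The
  ground truth `expected_slope(v) = Σ_k p_k(v) β_k` is the exact derivative
  of the mean model with respect to age.
- `η_ik ~ N(0, 0.5²)` (mm at bump peak): subject-level heterogeneity of
  regional aging; `γ_i ~ N(0, 0.15²)` mm: global offset;
  `ε_iv ~ N(0, 0.35²)` mm: fine-grained measurement noise.

Thickness is floored at 0.1 mm — cortex has a hard physical lower bound, and
with default parameters the floor touches at most a handful of the 768,600
cells per cohort. A specification that would floor more than 1% of cells is
rejected after one retry with 3-SD-truncated noise.

**Default geometry.** The reference scenario lives on an icosphere at
subdivision 4 (2,562 vertices) with radius 30 mm. The radius is a
scaled-down-geometry choice: with 12 latent components the inter-component
spacing is ~33 mm and the component width ~13 mm, so the 0–40 mm kernel grid
interacts with the aging structure the way it does with fine cortical
structure at full scale — kernels ≤10 mm are nearly harmless, kernels
≥20 mm merge neighbouring components. On a full-size (80 mm) sphere, 12
components would sit ~80 mm apart and no kernel in the grid could merge
them; the mechanism under study would be absent by construction.

**What the generator does not emulate**: cortical folding and its
gyral/sulcal thickness bias, hemispheric asymmetry, spatially correlated
measurement noise, nonlinear age trajectories, and site/sex covariates.
Passing tests therefore demonstrate that the estimators and the
association/prediction trade-off behave correctly under the assumed
linear-mixture model — not that effect sizes match any particular real
dataset.

## Smoothing

Diffusion (heat-kernel) smoothing realizes a large-FWHM Gaussian on a curved
surface by iterating a small one-ring step: n = ceil((FWHM/ē)²) steps of
width FWHM/√n, where ē is the mean edge length (widths add in quadrature).
Each step mixes vertex v with its neighbours using edge-length Gaussian
weights, and the neighbour mass λ_v is calibrated per vertex so the step's
realized second moment equals 2σ_step² — the second moment of an isotropic
2D Gaussian. The calibration matters: a truncated one-ring Gaussian without
it under-realizes the nominal width by ~25% at step = edge length. The step
operator is non-negative and row-stochastic, so constants are exactly
invariant, output stays within the input range, and the operation is linear.
Mean thickness is conserved exactly where the weights are symmetric (regular
grids) and to ~10⁻³ relative on icospheres. Verified behaviour: the impulse
response on a flat equilateral grid matches the analytic 2D Gaussian to
<2% relative RMS at FWHM ≥ 3 edge lengths, and kernel compositions agree
with single kernels of quadrature-summed width to well under 5%.

## Parcellation

Synthetic parcellations are geodesic Voronoi cells of farthest-point-sampled
seeds (deterministic given the seed; cells are connected by the
shortest-path property). Parcel means are unweighted vertex means — the
common convention on quasi-uniform surface meshes — with an area-weighted
option behind a flag. Macro regions (default 7, after the classical
cytoarchitectural territories) group parcel centroids by farthest-point
clustering; regional CV summaries average per-unit CV values (mean of CVs,
not CV of means).

## Resel estimation

The residuals of the per-vertex linear age model, normalized to unit sum of
squares, define the residual metric: for edge (u, v), the squared metric
length is Σ_i (r_iu − r_iv)². Each triangle's area in this metric follows
from its three squared sides by Heron's formula written in squared sides,
√(2(ab+bc+ca) − a² − b² − c²)/4; non-embeddable triangles (negative
discriminant) are clipped to zero and counted. Summing gives the 2D
Lipschitz–Killing curvature, and

    resels₂ = LKC₂ / (4 ln 2),  effective FWHM = √(search area / resels₂).

For a unit-variance Gaussian field smoothed at FWHM w this recovers w
(Var(∂u) = 1/(2σ²) for a Gaussian autocorrelation), which is the module's
acceptance-level check: applied kernels of 8/12/16 mm are recovered within
10% from 200 simulated maps. A finite-difference oracle — direct integration
of √det(Λ̂) from residual gradients on a flat grid — agrees with the
triangle sum to under 1%. No small-sample degrees-of-freedom correction is
applied to edge resls (n ≥ 200 in all shipped runs); only the 2D term is
computed, since the search space is a closed surface with no boundary.
Parcel-level conditions are first projected back to the surface
(parcel-constant maps), so their resels come entirely from parcel
boundaries.

## Brain-age prediction

Features are principal component scores of the (mean-centred) thickness
features; component signs are fixed by making each component's
largest-magnitude loading positive. Prediction is OLS of age on the first k
scores with intercept, under seeded 10-fold cross-validation repeated 5
times (repetition spread is <1% of the metric values, so few repetitions
suffice; configurable to 100). Fold assignment is keyed to sorted subject
ids, making all metrics invariant to row order.

**PCA inside or outside the folds.** Both policies are implemented. The
default is `global` (PCA fit once on all subjects, cross-validation applied
to the regression): the overfitting bias adj R²(k) − cv r²(k) is only a
measure of regression overfitting when both terms use the same feature
basis, and under this policy the bias is cleanly rank-increasing in k.
With `within_fold` PCA the feature basis changes per fold; basis
re-estimation absorbs part of the overfitting and, when eigenvalues are
nearly degenerate, fold bases can include age-informative components that
the fixed basis ranks beyond k — the bias curve then flattens and loses its
interpretation. The leakage the global policy admits (unsupervised basis
estimation on test rows) does not use test ages and is empirically
negligible here; users studying strict generalization can switch the policy
per call or in the grid config.

`adjusted R² = 1 − (1 − R²)(n−1)/(n−k−1)` is computed in-sample on the first
k global scores (k = 0 returns 0 by convention). `cv r²` is the squared
correlation of pooled cross-validated predictions with age, averaged over
repetitions; correlations of constant predictions are flagged undefined
rather than zeroed.

**Delta age.** δ₁ = predicted − chronological age, computed from
cross-validated predictions averaged over repetitions at the condition's
best k (minimum cross-validated RMSE). δ₂ is the residual of δ₁ on
(intercept, age) fit on the pooled estimates, hence exactly mean-zero and
age-orthogonal (machine precision). Cross-condition δ₂ similarity is the
Pearson correlation matrix over conditions.

## Condition grid

Order of operations per condition: smooth at the vertex level, then parcel
average, then analyze — and project parcel values back to vertices for resel
estimation. Per-condition prediction seeds derive from the grid seed via
`SeedSequence` so any condition can be reproduced in isolation; identical
configuration and seeds give byte-identical output tables. A failing
condition is recorded and the rest of the grid still runs. The comparison
table carries, per condition: median r², resels₂, effective FWHM, adjusted
R² and cv r² at the reference k = 30, best k with its RMSE, and macro-region
CV means; the cross-condition summary reports Spearman rank correlations for
(median r², resels₂), (adj R², resels₂) and (cv r², median r²).

Default grid: FWHM {0, 5, 10, 20, 30, 40} mm × {vertexwise, 300, 100}
parcels at icosphere subdivision 4 — 18 conditions, ~30 s on one CPU. The
paper-scale resolution list {vertexwise, 100, 200, 400, 1000} is a config
change, but 1,000 parcels on a 2,562-vertex mesh would average ~2.5 vertices
per parcel, so the default uses levels that are meaningfully distinct at
this mesh size.

## Numerical choices and degenerate inputs

- Zero-variance units get r = 0 with a degenerate flag and are excluded from
  median r²; perfectly fit vertices yield zero residual vectors, excluded
  from edge resls when both edge endpoints are degenerate.
- Two-sided p-values (thinning direction is not assumed universal a priori);
  Bonferroni m is the number of units tested at that level.
- Sample (n−1) standard deviations for σ and CV.
- fwhm = 0 is an exact identity everywhere.
- Step rule n = ceil((FWHM/ē)²) keeps step σ ≤ 0.43 ē, where the one-ring
  calibration is well-conditioned (λ_v ≤ 1).
- All randomness flows from integer seeds through `numpy` `SeedSequence`;
  same seed ⇒ bit-identical cohorts, parcellations, folds, and tables.

## Known limitations

- Graph geodesics overestimate true surface distance by up to ~15% in
  off-lattice directions; this slightly distorts bump shapes and parcel
  boundaries but cancels in all comparisons, which are within-mesh.
- The resel estimator assumes the residual field varies smoothly at the
  mesh scale; for unsmoothed white noise the effective FWHM reflects the
  mesh resolution rather than a physical smoothness.
- Parcel-level resel counts depend on the boundary geometry of the specific
  parcellation, not only the parcel count.
- The generator's linear age model cannot probe nonlinear-trajectory or
  covariate-confounding questions; those are out of scope.
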