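# Methods

## Model and procedure

The package treats a tumor as a mosaic of phenotypically coherent
subregions ("habitats") that are shared across a patient cohort.  Four
voxelwise channels describe local phenotype: lung-windowed CT (anatomy /
density), body-weight SUV (glucose metabolism), and the local Shannon
entropy of each (texture).  Habitat discovery is deliberately two-level:

* **Patient level.** Each tumor is over-segmented into superpixels by
  k-means on the vector (λx, λy, λz, c₁..c₄), restricted to tumor voxels.
  The spatial weight λ = compactness / d_eq, with d_eq the equivalent
  superpixel diameter (V/n)^⅓, keeps superpixels contiguous in the SLIC
  sense while letting intensity boundaries dominate.  K-means clusters are
  split into 26-connected components; fragments below `min_size` voxels are
  merged into the 26-adjacent superpixel with the nearest centroid, so the
  final map partitions the mask exactly.
* **Population level.** Each superpixel is summarized by 10 first-order
  statistics per channel — skewness, excess kurtosis, mean, median, first
  quartile, second quartile, interquartile range, SD, variance, energy —
  i.e. 40 features.  The canonical statistic list contains both "median"
  and "second quartile"; they are mathematically identical and both columns
  are kept so the table always has 40 aligned columns.  Pooled superpixels
  are z-scored, embedded in a k-nearest-neighbor graph (Euclidean, k = 20),
  reweighted by shared-nearest-neighbor Jaccard overlap (pruned below
  1/15), and partitioned by Louvain community detection.  Habitat ids are
  ordered by community size and are cohort-wide, so maps are comparable
  across patients.

Spatial architecture is quantified by the multiregional spatial interaction
(MSI) matrix: for every voxel carrying a habitat or border label, each of
its 26-connected labeled neighbors increments the corresponding cell;
border–border pairs are skipped.  Counting both directions makes the matrix
symmetric by construction, and the off-diagonal cell (i, j) equals the
number of unordered adjacent (i, j) voxel pairs.  The border label (index
0) is the ring of non-tumor voxels 26-adjacent to the mask, so the matrix
also measures how much of each habitat is exposed at the tumor boundary.
The 92-feature vector for K = 8 habitats concatenates 4 second-order
statistics of the normalized matrix, 8 volumes, 8 border interactions, 28
pairwise interactions, and normalized versions of the last 44 (percent
volume; interactions divided by the total unordered interaction count).
Patients whose tumors lack a habitat get zero-valued features so vectors
stay aligned across the cohort.

Subtypes come from consensus clustering: features are min-max scaled across
the cohort (otherwise count-scale features dominate every rank profile),
patients are compared by Spearman distance, and PAM — deterministic greedy
BUILD plus best-single-swap SWAP to convergence — is run on 500 random 80%
subsamples for each k in 2..5.  Consensus(a,b) is the fraction of
co-sampled draws in which a and b co-clustered.  The area A(k) under the
CDF of upper-triangle consensus values summarizes crispness; Δ(k) is A(2)
for k = 2 and the relative gain (A(k)−A(k−1))/A(k−1) afterwards, and the
chosen k is the largest with Δ(k) > 0.10 (ties resolve toward smaller k by
construction).  Final labels are PAM on (1 − consensus); the medoid feature
profiles define the subtype centers used to assign validation cohorts (a
new patient joins the medoid with smallest Spearman distance, ties toward
the lower cluster id).  Risk names (low / intermediate / high) are assigned
post hoc by ranking clusters on recurrence event rate; they are reporting
metadata, not part of clustering.

Survival evaluation delegates to lifelines: product-limit Kaplan–Meier
curves, the (g−1)-df log-rank test, Cox proportional-hazards fits with
Efron tie handling and Wald CIs (categorical covariates expanded against a
declared reference level; the high-risk subtype is the reference), and
Harrell's C over admissible pairs with score ties counted 0.5.  Nested
model comparison fits each covariate set, scores patients by the in-sample
linear predictor and reports C with a seeded 200-replicate patient
bootstrap CI.  Missing covariates trigger complete-case analysis with a
logged exclusion count; a covariate missing in more than 20% of patients is
an error.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| lung window center / width | −400 / 1500 | HU | standard lung window |
| SUV ceiling | 20 | SUV | uptake above this is clinically saturating; keeps the channel in [0,1] |
| entropy radius / bins | 1 voxel / 32 | — | see "numerical choices" |
| resample target | 1.0 | mm | isotropic common grid |
| superpixel target size | 100 | voxels | ~4.6 mm equivalent diameter, small vs habitat scale |
| compactness | 0.2 | — | intensity terms dominate; superpixels still contiguous |
| min superpixel size | 10 | voxels | statistics below this are too noisy |
| knn / SNN prune | 20 / 1/15 | — | common SNN-graph practice |
| Louvain resolution | 0.6 | — | see "numerical choices" |
| MTV threshold | 2.5 (absolute) or 0.4×SUVmax | SUV | the two standard MTV rules |
| consensus resamples / fraction | 500 / 0.8 | — | common consensus-clustering practice |
| elbow threshold | 0.10 | relative Δ-area | parsimonious k selection |
| Cox ties / tests | Efron / two-sided α = 0.05 | — | common defaults |

## What the phantom emulates — and what it does not

`phantom.PhantomSpec` plants an ellipsoidal tumor (default radii 18/14/12
mm on a 64³ 1-mm grid) whose voxels are partitioned into contiguous habitat
blobs by distance-ordered seeded region growth: each habitat claims the
frontier voxel nearest its seed, with habitats taken in order of remaining
deficit, so realized volume fractions hit their targets and blobs stay
compact, as real habitats are.  Eight habitats carry (CT mean, SUV mean,
CT SD, SUV SD) profiles spanning the qualitative phenotypes seen in
practice — dense low-uptake tissue (habitats 3–4), high-density
high-uptake tissue (habitats 7–8) — and the per-habitat SDs plant distinct
entropy levels, because habitats differ in texture as well as intensity.
Noise is a unit-variance mix of white and Gaussian-correlated fields
(correlation length 1.2 voxels, mixing weight 0.7), emulating
reconstruction-kernel texture.  Subtype mixtures put low-risk mass on
habitats 3–4, intermediate-risk on 5–6 and high-risk on 7–8 (with habitats
4 and 7 seeded near the border in high-risk tumors); per-patient fractions
are Dirichlet draws around the mixture (concentration 120), and per-patient
tumor radii are scaled by a U(0.85, 1.15) factor so tumor volumes vary
across the cohort.  Survival
times follow a proportional-hazards Weibull (shape 1.2, scale 60 months)
with subtype hazard ratios 0.38 (low) and 0.52 (intermediate) versus high
risk, independent U(0, 80 months) censoring applied to half the cohort,
and ctDNA clearance drawn per subtype (high risk: 67% Persistent; low
risk: 62% Never Detected; intermediate: 45% Cleared).  The full clinical
generator adds treatment (HR 2.0), metabolic tumor volume (HR 1.4 per SD
of log MTV), histology (HR 0.75) and a ctDNA clearance effect (Persistent
HR 3.0, Cleared 1.5 vs Never Detected) so subtype and ctDNA each carry
signal beyond the clinical covariates.

The phantom does **not** emulate scanner physics (partial-volume effects,
respiratory motion, reconstruction artifacts, attenuation), inter-site
protocol differences, registration error, segmentation uncertainty, or
habitats with gradual (non-blob) transitions.  Passing recovery benchmarks
therefore shows the pipeline's machinery is correct and its defaults are
coherent — not that real NSCLC cohorts will separate this cleanly.

## Numerical choices

* **Entropy kernel: ball radius 1, 32 bins over a fixed [0, 1] range.**
  Entropy of the windowed CT and scaled SUV is binned over the fixed
  harmonized [0, 1] range, never the per-volume range — per-volume binning
  shifts bin edges with each patient's extremes and injects cohort batch
  effects.  The radius is 1 voxel because a wider kernel mixes intensities
  across habitat interfaces: with radius 2 the mixed shell is two voxels
  deep, its superpixels form their own feature-space communities, and
  habitat maps fragment.  Radius 1 confines mixing to a single-voxel shell.
  Both radius and bin count are configurable.
* **Louvain resolution 0.6.**  On pooled cohorts of a few thousand
  superpixels, resolutions near 1 fragment each habitat-scale community
  into two or three; 0.6 matches the community scale to habitat-scale
  structure (on four-habitat phantoms: K ≈ 4–5, voxel ARI ≈ 0.97; on the
  eight-habitat default: K = 8).  Louvain runs on igraph with a seeded RNG,
  so results are reproducible.
* **Degenerate inputs.**  Constant-intensity volumes yield an all-zero
  entropy map with a warning; constant superpixels report skewness and
  excess kurtosis 0 (not NaN) and SD/variance/IQR 0; energy is the mean
  squared intensity; SD/variance are population (ddof 0) moments; a
  constant marginal in the MSI matrix sets correlation to 0 with a warning;
  a constant feature profile is an error in Spearman distance (ranks are
  undefined), detected by exact zero range.
* **Resampling** is trilinear for intensities and nearest-neighbor for
  masks/labels (no new label values), grid anchored at the input origin,
  physical extent preserved to within one voxel.  Registration is out of
  scope: volumes must share a grid after resampling and a hard check
  rejects mismatches.
* **PAM determinism.**  BUILD seeds with the 1-medoid optimum and adds the
  point with the largest cost reduction; SWAP applies the single best
  improving exchange per iteration (max 100).  Given a distance matrix the
  result is fully deterministic; argmin ties resolve to the lowest index.
* **Consensus edge cases.**  Patient pairs never co-sampled get consensus 0
  with a warning; a patient never sampled at all is an error asking for
  more resamples.

## Problem sizes in tests and the acceptance script

Recovery benchmarks run at desk scale: habitat recovery uses 20 patients at
64³ (the four-habitat spec); subtype recovery uses 90 patients with tumor
radii 14/11/9 mm and 200 consensus resamples (smaller tumors and fewer
resamples than the 500-resample default keep the benchmark brisk without
changing its behavior); Cox coverage uses 100 replicates at n = 300;
log-rank calibration uses 500 null simulations; model-comparison ordering
uses 10 cohorts of n = 400.  The acceptance script reports subtype
recovery over 5 seeds.

## Known limitations

* Habitat count K is emergent from Louvain modularity, not fixed; cohorts
  with different composition can yield different K, and cross-cohort
  habitat matching (beyond pooling) is limited to a centroid-based check.
* The MSI normalization denominator (total unordered interaction count) and
  the inclusion of the border row/column in the second-order statistics are
  package conventions; other implementations may normalize differently, so
  absolute normalized-feature values are comparable only within one
  convention.
* `assign_subtype` transfers labels by medoid proximity; it presumes the
  validation cohort's features were computed with the same habitat
  definitions and scaling.
* The survival machinery assumes proportional hazards and right censoring;
  competing risks and time-varying covariates are out of scope.
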