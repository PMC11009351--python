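# habitatpet

Tumor *habitat imaging* for co-registered PET/CT: discover intratumoral
subregions ("habitats") from fused anatomic, metabolic and texture channels,
quantify their spatial architecture, derive imaging subtypes, and evaluate
those subtypes against survival endpoints and circulating tumor DNA (ctDNA)
status.  The package is aimed at quantitative-imaging researchers studying
recurrence risk in resectable non-small-cell lung cancer (NSCLC) and related
settings, and ships a phantom module so every stage runs and is testable on
fully synthetic data.

## The method

Given a CT volume (Hounsfield units), a PET volume (activity or SUV) and a
binary tumor mask on a common grid:

1. **Harmonization** — CT is lung-windowed to [0, 1]; PET activity is
   converted to body-weight standardized uptake value,
   SUVbw(v) = A(v) / (D/w) with injected dose D (Bq) and body weight w (g);
   both are resampled to 1 mm isotropic; local Shannon entropy maps
   E(v) = −Σ_b p_b log₂ p_b of the normalized CT and SUV provide two texture
   channels.
2. **Habitat discovery** — the four channels (CT, CT entropy, SUV, SUV
   entropy) are fused; each tumor is over-segmented into ~100-voxel
   superpixels by k-means on intensity + spatial coordinates; 10 first-order
   statistics per channel (40 features) summarize each superpixel; pooled
   superpixels from the whole cohort are clustered into population-level
   habitats with Louvain community detection on a shared-nearest-neighbor
   graph.
3. **Spatial quantification** — the multiregional spatial interaction (MSI)
   matrix counts 26-connected voxel-pair co-occurrences among habitat labels
   plus a tumor-border label.  For the canonical K = 8 habitats this yields
   92 features: 4 second-order statistics of the normalized matrix
   (contrast Σ P(i,j)(i−j)², homogeneity Σ P(i,j)/(1+|i−j|), marginal
   correlation, energy Σ P(i,j)²), 8 absolute habitat volumes, 8 + 28
   habitat–border and pairwise interaction counts, and the same 44
   quantities normalized (percent volume; per-pair interaction fractions).
4. **Imaging subtypes** — consensus clustering of per-patient MSI vectors:
   PAM (partitioning around medoids) with the Spearman distance
   d(a,b) = 1 − ρ(a,b) on repeated 80% patient subsamples for k = 2..5; the
   number of subtypes is chosen from the CDF of consensus values by the
   delta-area elbow rule; medoids let new cohorts be assigned.
5. **Clinical evaluation** — Kaplan–Meier curves and log-rank tests,
   univariate/multivariate Cox proportional-hazards models (Efron ties),
   Harrell's C-index with bootstrap CIs for nested model comparison, and
   subtype × ctDNA cross-tabulations (Persistent / Cleared / Never
   Detected).

## Worked example

`examples/` holds one short script per capability.  Habitat discovery on a
six-patient synthetic cohort (`python examples/02_habitat_discovery.py`):

```
P0000: 156 superpixels
...
pooled 932 superpixels -> 4 habitats
P0000: voxel ARI vs planted habitats = 0.982
P0001: voxel ARI vs planted habitats = 0.971
P0002: voxel ARI vs planted habitats = 0.983
```

The phantom plants 4 habitats per tumor; the pipeline pools 932 superpixels,
finds 4 population-level communities, and the per-patient adjusted Rand
index (~0.98) says the rendered habitat maps agree almost voxel-for-voxel
with the planted truth.

Clinical evaluation on a 400-patient synthetic cohort
(`python examples/05_survival_and_ctdna.py`):

```
log-rank across subtypes: chi2=115.5 (df=2), p=8.30e-26

Cox model (high-risk subtype = reference):
  subtype[intermediate]    HR=0.31 (0.23-0.43)  p=2.79e-13
  subtype[low]             HR=0.19 (0.13-0.27)  p=1.21e-19
  ...
Harrell's C per model (95% bootstrap CI):
  clinical                         C=0.591 (0.554-0.624)
  clinical+volume+subtype          C=0.720 (0.683-0.748)
  clinical+volume+subtype+ctdna    C=0.741 (0.715-0.766)
```

Lower hazard ratios for the low/intermediate subtypes mean longer
recurrence-free survival than the high-risk reference; each added covariate
block raises the concordance of the risk model.

A thin CLI mirrors the library (`habitatpet simulate|preprocess|habitats|
msi|subtype|survive|run-all --config cfg.yaml`); every run writes a manifest
with SHA-256 hashes so reruns are bit-for-bit reproducible.

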