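# Methods

This note documents the statistical models, parameter defaults and design
decisions behind `radiotsh`, and what the synthetic-data experiments do and
do not establish.

## Cell-population abundance and the TSH statistic

Abundance of a cell population `c` in sample `s` is the arithmetic mean of
`log2(x + 1)` over the population's marker genes (the MCP-counter
estimator family).  The `+1` pseudo-count keeps zero counts finite; the
log2 transform is applied to linear-scale expression.  Genes that are zero
or missing in ≥ 80% of samples are removed first; missing values that
survive the filter are excluded from the per-gene mean rather than
imputed, matching the filter's tolerance of sporadic missingness.  Real
marker lists are not shipped: the GMT interface accepts any disjoint
lists, and the estimator's contract (marker-mean of log2 expression) is
what is tested.  A cell type with no marker present in a matrix is an
error, never a silent value.

The TSH statistic is `(A_tumor − A_stroma)/A_stroma`, undefined when the
stromal abundance is below a configurable epsilon (an error naming the
offending patients).  It is scale-invariant and dimensionless.
Stratification uses `tsh > threshold → good`, ties to poor (the
published threshold 0.3512 ships as a constant; its derivation — e.g. an
optimal cut-point search — is outside this package's scope, so it is
treated as a user-supplied parameter).

## Survival statistics

Kaplan–Meier, two-group log-rank and Cox proportional-hazards fits are
delegated to lifelines; ties use Breslow's method (ties are rare in
continuous follow-up).  The Wald column reports the squared z statistic
(chi-square, 1 df).  Follow-up is administratively censored at 10 years.
The likelihood-ratio test compares nested Cox models via `2·Δlog L`
against chi-square with the parameter-count difference.  Benjamini–
Hochberg adjustment is applied across the ten cell populations in the
univariate sweep.  The Wilcoxon signed-rank test discards zero
differences (standard convention), uses the exact null for ≤ 25 remaining
pairs and the continuity-corrected normal approximation above; all-zero
differences are flagged and return p = 1.

## Cell-correlation networks

Within one (survival group, region) stratum, nodes are the ten cell
populations and an edge joins pairs with Pearson correlation across
patients strictly greater than 0.5.  The threshold is *signed*: strong
negative correlations do not form edges, as the edge rule is stated as a
plain correlation threshold.  Topology follows Cytoscape
NetworkAnalyzer conventions, which is why the panel has nine parameters
(the listed eight plus mean degree, Cytoscape's "avg. number of
neighbors"):

* node number counts only nodes with degree ≥ 1 (edge-list import
  semantics — this is why node counts can differ between groups despite
  ten populations);
* density = 2E/(n(n−1)) over those nodes; mean degree = 2E/n;
* diameter and characteristic path length are computed on the largest
  connected component;
* the clustering coefficient is the mean local clustering over nodes of
  degree ≥ 2;
* centralization = [n/(n−2)]·[max_deg/(n−1) − density] (Freeman-style);
* heterogeneity = sd(degree)/mean(degree) (population variance).

Degenerate cases (no edges, n ≤ 2) return 0 for the undefined metrics.

## Image preprocessing

Volumes are resampled to 0.8 × 0.8 × 2.0 mm (trilinear for intensities,
nearest-neighbor for masks) and normalized by the mean intensity of the
parenchyma.  Parenchyma defaults to breast − (tumor ∪ stroma band) when
no explicit mask is supplied.  Phase maps are S0, S_I = intermediate
postcontrast − S0 and S_L = last − S0; the intermediate index is
⌈k/2⌉ (1-based) among k ∈ [3,6] postcontrast volumes — a documented,
configurable choice since any of k = 3..6 needs a deterministic middle.
Segmentation runs on S_I by default (strongest tumor contrast),
configurable.

### Spatial fuzzy c-means

Two-class FCM (fuzzifier m = 2) on intensities within the breast mask,
initialized from intensity quantiles with the seed voxel's intensity
injected as a warm start.  After each standard membership update, each
membership map is multiplied by its 3×3 in-plane neighborhood average
raised to `spatial_weight` (default 1) and renormalized — the
membership-averaging member of the spatial-FCM family; `spatial_weight=0`
recovers classic FCM exactly.  Iteration stops when the centroid shift
drops below 1e-4 (max 200 iterations; non-convergence returns the best
iterate with a warning).  The tumor class is the seed voxel's class; the
output mask is the connected component of the thresholded (> 0.5)
membership containing the seed.  The breast mask (skin/chest-wall
removal) is an input; automatic breast segmentation is out of scope.

### Peritumoral stroma band

Per-slice 2D morphological dilation of the tumor by a disk of radius 25
voxels (20 mm at 0.8 mm in-plane), minus the tumor, intersected with the
breast.  Dilation is 2D because the band width is specified in in-plane
units and 3D dilation would be anisotropic at 2 mm slice thickness.
Mask invariants (tumor ∩ stroma = ∅, both ⊆ breast) are enforced.

## Radiomic features (572)

18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM = 93
features per (region, phase) for tumor/stroma × S0/S_I/S_L, plus 14 shape
features of the tumor mask: 6 × 93 + 14 = 572.  Names follow the stable
schema `<region>_<phase>_<family>_<feature>` / `tumor_shape_<feature>`
(schema version 1; the order is fixed so downstream models reproduce).

Numerical conventions, fixed and configurable:

* discretization: equal-width binning of the in-ROI range into 32 gray
  levels — a fixed bin *count* keeps normalized features comparable
  across subtraction phases whose ranges differ;
* texture matrices: 13 unique 3D directions at distance 1; GLCM is
  symmetrized; GLCM/GLRLM matrices are normalized/averaged over
  directions before features are computed;
* GLDM dependence size = 1 + number of 26-neighbors within `alpha`
  (default 0) gray levels — counting the center as self-dependent keeps
  the small-dependence denominators finite for isolated voxels;
* percentiles use linear interpolation; first-order entropy/uniformity
  use the 32-bin histogram;
* shape: surface/volume from a marching-cubes mesh of a lightly smoothed
  (σ = 1 voxel) mask — meshing the raw binary mask overestimates smooth
  surfaces by ~8% (staircase bias); axis lengths are 4·√eigenvalue of
  the physical-coordinate covariance; flatness = √(λ_least/λ_major);
* degenerate (constant-intensity) ROIs are flagged and texture features
  take their analytic limits (e.g. IDMN = 1, NGTDM contrast = 0).

Every family is cross-checked against naive per-voxel enumeration
oracles on random small grids; GLCM/GLRLM direction averaging makes the
features invariant under 90° in-plane rotation, which is asserted.

## Signature modelling

Collinearity pruning greedily removes, from the worst-correlated pair,
the feature with the larger mean absolute correlation (ties by name),
until no pair exceeds |r| = 0.8.  Absolute correlation is used even
though the rule is often quoted as `r > 0.8`: anti-collinearity equally
concerns strong negative correlation.

The GA selector uses binary-mask chromosomes, tournament selection
(size 3), uniform crossover (rate 0.8), per-bit mutation (rate 1/n
features) and single elitism; fitness is the mean out-of-fold AUC of a
random forest over stratified folds, cached per chromosome.  The
reference configuration is population 100, 100 generations, tenfold CV;
simulation experiments in the test-suite and acceptance script run a
scaled configuration (population 16, 8 generations, 3 folds, 40-tree
forests) — planted-signal recovery is already saturated at that size.
Under the null, the GA's own best fitness is optimistically biased
(winner's curse over ~10² masks, ≈ 0.65 at n = 200); the honest null
quantity reported is the selected subset's CV AUC re-estimated on an
independent fold split, which stays near 0.5.

The imaging TSH score is the random forest's predicted probability of
the poor class (higher = poorer predicted survival), thresholded at 0.5
for prognostic grouping.  Prognostic validation joins scores to survival
records, censors at 10 years, and reports Kaplan–Meier curves, the
log-rank test, the signature's hazard ratio adjusted for age, ER, PR,
HER2 and tumor size (receptor status coded 1/0 with 0.5 for missing),
and the likelihood-ratio test against the clinical-covariates-only
model.  A single pipeline seed fans out deterministically to GA, folds
and forests; fixed seeds give bit-identical selected-feature lists.

## Synthetic-data generators

The generators define the study conditions for every experiment.

**Expression cohorts.**  Marker genes of population `c` in region `r`
are drawn as `planted(c, r, group) + latent_patient + N(0, noise_sd)`
on the log2 scale (default noise 0.3); linear values are `2^v − 1` so
noise-free cohorts round-trip exactly through abundance estimation.
The planted pattern mirrors the paired-cohort phenomenon the pipeline
targets: in the good-survival group every population is 1.5× more
abundant (log2 scale) in tumor than stroma (TSH = +0.5); in the poor
group the tumor is depleted to 0.6× (TSH = −0.4).  The patient latent
factor (sd 0.5 in the good group, 0.05 in the poor group) induces
inter-cell-type correlation of ≈ 0.97 vs ≈ 0.22 — chosen a priori from
the implied correlation formula so that the two groups fall clearly on
either side of the 0.5 edge threshold.  Non-marker genes are
group-independent log-normal background.  What this does *not* emulate:
TCGA batch effects, compositional coupling between populations,
marker-gene cross-talk, or realistic library-size variation — passing
tests show estimator/statistic correctness, not robustness to those.

**Phantoms.**  Ellipsoidal tumor inside an ellipsoidal breast on a
0.8 × 0.8 × 2 mm grid (default 96 × 96 × 16).  Tissue intensity is
`base · (1 + amplitude · GRF) · curve[t]` plus base-scaled
time-constant noise, where the GRF is a unit-variance Gaussian random
field smoothed at σ = 2 mm; the default enhancement curves peak the
tumor at ≈ 2× precontrast with mild washout and let parenchyma ramp
weakly, giving a two-tissue contrast of ≈ 2:1 on S_I with noise ≈ 5% of
that contrast.  A flat curve yields bitwise-identical volumes (so the
subtraction phases vanish exactly).  No scanner physics, bias fields,
motion, or anatomical realism are modelled.

**Survival.**  Exponential event times; the poor group's hazard is
`baseline_hazard` (0.15/year) × `hazard_ratio` (3).  Censoring times are
independent exponentials with rate `rate · c/(1 − c)` so the expected
censored fraction is exactly `censor_rate` (0.3) while censoring stays
conditionally independent of the event time — an earlier scheme that
censored at a uniform fraction of the event time was informative and
biased Cox coverage several points low, which is why this one is used.
Clinical covariates are simulated independently of survival; they
exercise the adjusted models' design matrix, not confounding.

## Experiment sizing

The simulation studies use: 100 replicates at n = 500 for Cox coverage
of the planted log hazard ratio (2-SE criterion, nominal 95.4%);
1000 null simulations at n = 100 for log-rank type-I error; 10 GA seeds
at n = 200 with 20 noise features for planted-feature recovery; 50
random grids ≤ 5×5×3 per texture family for oracle agreement; all
graphs on ≤ 6 nodes (up to isomorphism, via the networkx atlas) for
topology; and exhaustive enumeration for AUC (≤ 10 samples) and the
exact Wilcoxon null (2⁶ sign patterns).

## Known limitations

* Shape features inherit marching-cubes discretization error; sub-voxel
  accuracy is not attempted.
* The spatial-FCM variant is one member of a family; with
  `spatial_weight > 0` the classic FCM objective is no longer the exact
  Lyapunov function of the iteration (monotonicity is asserted for the
  plain-FCM path).
* Texture features on strongly degenerate ROIs (a handful of voxels, one
  gray level) are limit values, not estimates.
* The GA explores a tiny fraction of 2^p masks; it is a stochastic
  heuristic and only seed-level determinism is guaranteed.
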