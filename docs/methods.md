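# Methods

`atroprop` implements a post-parcellation analysis pipeline for cortical
atrophy progression in Alzheimer's disease and familial-risk (FHAD)
cohorts, together with a synthetic-cohort generator that makes every stage
testable against known ground truth.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Data model

All analyses operate on *parcellated* quantities: one scalar per cortical
region (e.g. the 448-region Cammoun scale in the motivating literature, or
any custom region set).  Region identity is an ordered list of string ids
carried by every object; operations refuse misaligned inputs rather than
reindexing, because a silent misalignment between a deformation map, a PET
map and a connectome row is the most dangerous failure mode in this kind of
pipeline.  Missing regional values are NaN, reported through
`missing_mask`, and handled pairwise-complete in correlations.  The region
missing-data policy is a repository convention: the emulated study designs
do not state one.

Deformation values are oriented at load time so that *larger = more
atrophy*; every downstream sign convention (W-scores, progression betas)
inherits this.

## W-scores (normative baseline atrophy)

Per region, a least-squares regression of the deformation measure on age
and sex (coded M=0, F=1; coding stored in the model artifact) is fit on
healthy-control *baseline* scans only, and any scan is scored as

    W = (observed − predicted(age, sex)) / residual SD .

The residual SD uses the unbiased `n − 3` denominator (three parameters).
The reference regression includes exactly age and sex — no further
covariates — matching the normative-model convention for baseline atrophy.
In-sample HC W-scores have per-region mean 0 to ~1e-15 by construction,
and W is invariant to affine rescaling of the raw measure (the scale
cancels between numerator and refit residual SD).  Ages more than 10 years
outside the reference range trigger an extrapolation warning rather than an
error.

## Regional progression model

The atrophy-progression estimate is the group × age interaction
coefficient from a per-region linear mixed model:

    y ~ group + age + group:age + sex + education + BMI + APOE4 + APOE4:age
    random effects: intercept and age slope per subject,
    unstructured 2×2 covariance, REML.

Age is centered at the pooled baseline mean before entering the model
(units of the coefficients are unchanged); this is purely for conditioning.
The healthy-control group is the reference level and the three pairwise
contrasts (FHAD−HC, AD−HC, AD−FHAD) are reported explicitly; the third is
the exact linear combination of the first two, with its SE from the
coefficient covariance.  A positive beta means faster deformation change
with age than controls.

The omnibus group × age test is a Wald test on the two interaction
coefficients; we report W/2 as an F-like statistic and take p from the
chi-squared(2) reference distribution (the large-sample equivalent of the
Wald F).  Scans with missing covariates are dropped, not imputed.

Hundreds of independent regional fits need an automated non-convergence
policy.  The ladder is: unstructured random-effect covariance → independent
(diagonal) random effects → random intercept only, each step flagged in the
result (`covariance_structure`, `converged`).  Optimization tries L-BFGS
then conjugate gradients.  A region failing every rung is excluded and
listed.  One caveat found during development: the REML surface becomes
badly conditioned when the random-effect-to-residual variance ratio is
extreme (~100), so the simulator defaults keep that ratio moderate; real
data with near-degenerate random effects will simply fall down the ladder.

Multiple-comparison control is Benjamini–Hochberg throughout (`bh_fdr`,
q = 0.05 by default).  Post hoc contrast p-values are FDR-corrected within
the omnibus-significant region set; correcting over all regions instead is
available via `posthoc_scope="all"` (the literature leaves this choice
ambiguous).

Network-level progression averages regional values within each partition
label per scan and runs the identical mixed model on the (seven) network
means, with FDR over networks.

## PET group comparison and partial Spearman correlations

Baseline PET (one scan per subject) is compared between two groups by
region-wise OLS of SUVR on group plus age, sex, education, BMI and APOE4,
with the group-coefficient t-test and BH-FDR over regions.

Cognition–atrophy associations use partial Spearman correlations: all
variables are rank-transformed, the ranks residualized on the covariate
ranks (baseline age, BMI, APOE4 by convention), and Pearson correlation
taken on the residuals; two-sided p from the t reference with n − 2 − k
degrees of freedom, FDR across networks.  The implementation is
cross-checked against `pingouin.partial_corr` in the test suite.

## Categorical checks

The sex-by-group comparison is a Pearson chi-squared on the 2×2 table
*without* continuity correction (this is the variant that reproduces the
published statistic for the AD-vs-HC table), and the scans-per-subject
comparison is a tie-corrected Kruskal–Wallis H across the three groups.

## Spatially constrained null models

Parcellated brain maps are spatially autocorrelated, so parametric p-values
for map–map correlations are badly anticonservative (the test suite
measures a ~3× inflation of the nominal 5% rate on matched smooth fields).
Significance is therefore assessed against variogram-matched surrogate
maps:

1. permute the source map's values;
2. smooth the permuted map by distance-weighted averaging over each
   region's k nearest neighbors (truncated exponential kernel with
   bandwidth equal to the k-th neighbor distance), for a grid of candidate
   k;
3. regress the source's smoothed empirical variogram on each candidate's
   (25 bins spanning distances up to the 75th percentile, Gaussian-smoothed
   across bins) and keep the k minimizing the SSE;
4. surrogate = sqrt(|beta|)·smoothed + sqrt(|alpha|)·iid noise;
5. rank-remap the surrogate values onto the source's exact value multiset
   (default on, so surrogate and source are identical as distributions).

The candidate grid is k/R ∈ {0.02, 0.05, 0.1, …, 0.9}.  The two smallest
fractions are essential: without them surrogates cannot reproduce steep
short-range autocorrelation and the variogram fidelity drops from ~0.92 to
~0.85 on the 20-mm reference field.  The spin p-value is two-sided with the
+1 correction, p = (1 + #{|r_null| ≥ |r_emp|})/(n_surr + 1), so it is
floored at 1/(n_surr + 1) and never exactly zero.  By convention the
*first* map of a pair (the atrophy/progression map) is the one surrogated;
a symmetry test in the suite confirms the choice is immaterial for maps
with matched autocorrelation.  "Spins" here always means variogram-matched
surrogates — true spherical-rotation nulls are out of scope because parcel
sphere coordinates are not part of the data model.  Ensembles are
deterministic given (map, distances, seed, parameters) and are generated
once per target map and reused across candidate maps, so every candidate
faces the identical null.

## Neighbor-spread statistic

For a map x and a binary connectome A, the connected neighbor mean of
region i is the mean of x over {j ≠ i : A_ij = 1}, and the non-connected
mean is over {j ≠ i : A_ij = 0}.  The spread statistic is the Pearson
correlation of x with each across regions.  Under network-spread the
connected correlation is positive and the non-connected one negative.

Zero-neighbor regions are excluded listwise from *both* correlations so
the paired contrast uses identical samples.  In the surrogate null, the
surrogate map is pushed through the same neighbor-averaging operator before
correlating — the operator is part of the statistic, so it must be inside
the null.  Surrogates are generated on the retained region set but embedded
back into the full region vector so that neighbor means still see the
observed values of excluded regions.

Group-consensus connectomes retain an edge present in ≥ 50% of subjects by
default (`retain_fraction` exposed); a distance-binned variant preserves
the subject-mean edge count per edge-length bin for analyses where the
consensus graph's length distribution matters.

## Receptor colocalization and correlation comparisons

Receptor/transporter maps are z-scored per tracer study and combined per
target as a weighted average with weights proportional to study sample
size.  Colocalization against atrophy/progression maps uses the shared
surrogate machinery with BH-FDR across the candidate set per target.

Correlation strengths are compared with:

* **Fisher's z** for independent samples (between-group comparisons):
  z = (atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3));
* **Zou's modified-asymptotic CI** for dependent correlations (within-group
  comparisons sharing a map), in both the overlapping (one shared
  variable) and non-overlapping variants.  The dependence enters through
  the standard correlation-of-correlations formulas; with zero dependence
  the interval reduces exactly to the independent corner combination,
  which the test suite verifies in closed form, and simulation shows ~95%
  coverage at n = 448.  Supplied cross-correlation structures are checked
  for positive semidefiniteness.

## Synthetic cohort generator

The generator is first-class, tested code.  It emulates:

* **Geometry**: R points on two mirrored hemispheric shells of radius
  65 ± 5 mm; even R splits exactly in half.
* **Connectome**: edges drawn with probability ∝ exp(−d/30 mm), rescaled to
  a 15% target density, required to land within ±20% of the target with a
  giant component ≥ 90% of regions.
* **Ground-truth pattern**: degree-normalized diffusion
  Σ_k decay^k (D⁻¹A)^k s from seed regions, rescaled to unit maximum.
  Default seeds are an epicenter-like spatial cluster (a random region plus
  its nearest neighbors, 10% of R): focal nucleation is both the
  biologically sensible choice and necessary for the pattern to be
  detectably connectome-coupled — scattered seeds produce a spiky map whose
  neighbor-spread signal is weak.  Defaults `steps=8, decay=0.9` spread a
  graded gradient over the whole cortex.
* **Longitudinal deformation**: per subject and region,
  y = a_i + u_j + (slope_base + slope_effect_g·pattern_i + v_j)·age
  + covariate effects + site shift + ε, with subject random intercept
  u_j ~ N(0, 0.01²), random slope v_j ~ N(0, 0.001²), measurement noise
  ε ~ N(0, 0.005²), and a spatially autocorrelated intercept field a_i
  (exponential covariance, λ = 20 mm, via Cholesky).  Baseline ages are
  uniform within group-specific ranges mirroring the emulated cohorts
  (means ≈ 72–73 y); visits are 1 year apart with geometric dropout
  (p = 0.2/visit).  Covariate effects (sex, education, BMI, APOE4) default
  to small nonzero values so adjustment is actually exercised; APOE4
  allele-count probabilities differ by group as in the emulated cohorts.
* **PET maps**: SUVR = 1 + gain_g·pattern + smooth noise, gain 0.30 (AD)
  vs 0.15 (FHAD).
* **Receptor maps**: coupling·z(pattern) + sqrt(1−coupling²)·smooth field,
  z-scored; couplings default to 0.5/0.3/0.4 for the serotonin 5-HT6,
  5-HT1B and glutamate mGluR5 targets and 0 for the rest, and two targets
  are represented by two synthetic tracer studies to exercise the weighted
  average.
* **Subject connectomes**: each subject drops group edges at a 5% rate and
  gains an equal expected number of spurious edges, so consensus
  construction has realistic disagreement at calibrated density.
* **Network partition**: a spatially coherent 7-network parcellation
  (k-means on |x|, y, z, so homologous mirrored regions share a network),
  standing in for the canonical resting-state networks in network-level
  progression summaries.

Deformation units have no published scale, so the slope parameters
(slope_base = 0.01/y; slope_effect 0.04 for AD, 0.015 for FHAD) and noise
scales are calibrated for *test power*, not physiological realism: they are
chosen so that a 50-per-group, 3-visit cohort at R = 200 recovers the
ground-truth beta map with rank correlation ≳ 0.95 and detects
network-spread with high probability.  The random-effect-to-noise variance
ratio is kept moderate for REML conditioning (see above).  Everything is
reproducible bit-for-bit from `rng_seed` through a spawned seed-sequence
tree, and site effects default to off (harmonized-table emulation); setting
`site_shift_sd > 0` injects them for robustness checks only.

**What the synthetic data do not show.**  The generator is linear in age
within subject, Gaussian in every noise source, uses a single connectome
per group, and couples PET/receptor maps to the *same* pattern that drives
deformation.  Passing tests therefore demonstrate correctness of the
statistical machinery under the model's own assumptions — not robustness
to nonlinear trajectories, heavy-tailed noise, registration artifacts, or
atrophy–pathology decoupling in real cohorts.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
as the package's own verification protocol: beta-map recovery at R = 200
with 50 subjects/group and 3 visits; FDR calibration pooled over 10 null
cohorts of 40 regions and 30 subjects/group; held-out W calibration
averaged over 25 replicate control cohorts of 100 train / 100 test
subjects (averaging across replicates estimates the per-region calibration
to ±0.02, which a single n = 100 cohort cannot); surrogate fidelity on a
λ = 20 mm field at R = 200 with 100 surrogates; spin-test calibration over
400 independent field pairs at R = 120 with 200 surrogates each;
neighbor-spread power over 100 pattern draws and type-I error over 200
decoupled smooth maps at R = 200 with 99 surrogates; Zou CI coverage over
800–2000 replicates at n = 448.

## Known limitations

* Wald/chi-squared inference for the mixed model is large-sample; no
  Satterthwaite or Kenward–Roger small-sample correction is implemented.
* The surrogate generator assumes a complete, finite map; missing regions
  are handled by restriction, which slightly perturbs the distance
  distribution the variogram sees.
* The distance-binned consensus variant uses quantile bins of the pooled
  subject edge-length distribution; with very few subjects the per-bin
  quotas are noisy.
* True spherical-rotation ("spin") nulls, voxel-level processing,
  harmonization, and tractography are all out of scope; the pipeline
  starts and ends at parcellated tables.
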