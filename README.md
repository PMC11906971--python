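# atroprop

Cortical **atro**phy **pro**gression mapping on parcellated neuroimaging
data: normative W-scores, region-wise longitudinal mixed models, connectome
neighbor-spread statistics with spatially constrained null models, and
receptor-map colocalization — with a synthetic cohort generator so the whole
pipeline is testable against known ground truth.

## Who this is for

Researchers studying neurodegeneration with parcellated regional data — one
scalar per cortical region per subject per visit (deformation-based
morphometry, cortical thickness, tau/amyloid PET SUVR) — who want to answer
three questions about a disease or at-risk cohort (e.g. cognitively normal
people with a family history of Alzheimer's disease) relative to controls:

1. **Where is atrophy, and how fast is it progressing?**  Baseline atrophy
   as W-scores; progression as the group × age interaction of a linear
   mixed model fit per region.
2. **Does the spatial pattern follow the structural connectome?**  The
   neighbor-spread statistic with variogram-matched surrogate nulls.
3. **What does the pattern colocalize with?**  PET pathology maps and
   neurotransmitter receptor/transporter densities, with spin p-values and
   formal correlation-strength comparisons.

The pipeline starts strictly *after* image processing: inputs are delimited
text tables (TSV/CSV), dense adjacency matrices and coordinate tables.

## The statistics at the core

**W-score** (baseline atrophy, control-SD units), per region *i*:

    W_ij = (y_ij − (β̂₀ᵢ + β̂ₐᵢ·ageⱼ + β̂ₛᵢ·sexⱼ)) / σ̂ᵢ

with the regression fit on healthy-control baseline scans and σ̂ᵢ the
residual SD (n−3 denominator).

**Atrophy progression**, per region: the group × age coefficient β from

    y ~ group·age_c + sex + education + BMI + APOE4 + APOE4·age_c
        + (1 + age_c | subject),   REML, unstructured random covariance

with HC as reference; β > 0 means faster deformation change with age than
controls.  Omnibus group × age Wald test, Benjamini–Hochberg FDR across
regions (q = 0.05).

**Neighbor-spread**: Pearson correlation across regions between a map x and
the mean of x over each region's structurally connected neighbors (and,
as a specificity contrast, its non-connected regions).  Significance from
**variogram-matched surrogate maps**: value-permuted, k-nearest-neighbor
smoothed, variogram-refit null maps that preserve the empirical spatial
autocorrelation; p_spin = (1 + #{|r_null| ≥ |r_emp|}) / (n_surr + 1).

**Correlation-strength comparisons**: Fisher's z for independent samples;
Zou's modified-asymptotic CI for dependent (overlapping or
non-overlapping) correlations.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import atroprop as ap
from scipy import stats

cfg = ap.SimulationConfig(R=40, n_per_group=40, visits=3, rng_seed=5)
sim = ap.simulate_cohort(cfg)

res = ap.progression_maps(sim.dataset, q=0.05)
print(f"{res.fdr.n_rejected}/{len(res.table)} regions significant")

rho = stats.spearmanr(res.beta_maps["AD-HC"].values,
                      sim.ground_truth.true_beta["AD"]).statistic
print(f"rank correlation with ground truth: {rho:.3f}")

spread = ap.spread_test(sim.ground_truth.pattern,
                        sim.ground_truth.connectome, n_surr=500, rng_seed=1)
print(f"connected r = {spread.connected.r_emp:+.3f}, "
      f"p_spin = {spread.connected.p_spin:.4f}")
```

prints (seed-for-seed reproducible):

```
32/40 regions significant
rank correlation with ground truth: 0.894
connected r = +0.776, p_spin = 0.0080
```

32 of 40 regions show a significant group difference in progression after
FDR; the estimated per-region progression map orders the cortex almost
exactly like the generating pathology pattern (ρ = 0.89 even at this small
40-region scale); and the pattern
correlates strongly with its connected-neighbor means, beyond what
spatially matched surrogate maps produce.

The `examples/` directory has one short narrative script per capability
(simulation, W-scores, progression maps, network spread, colocalization),
and the `atroprop` command line exposes the same stages as a reproducible,
manifest-logged pipeline:

```bash
atroprop all --out run/ --seed 3 --n-surrogates 200
```

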