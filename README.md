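# plaquemorph

Quantitative vessel-wall MRI analysis of **non-stenotic intracranial
atherosclerotic plaques** (<50% luminal stenosis), for neuroimaging
researchers who want a tested, scriptable version of the standard
culprit-vs-non-culprit workflow: contour-based plaque morphometry,
first-order signal/histogram features, and the full case-control
statistical pipeline (univariate tests, logistic regression with odds
ratios, single and combined ROC analysis, inter-reader agreement).

Segmentations enter as ordered lumen and outer-wall contour polygons per
cross-section — at the most-stenotic site, at proximal/distal reference
sites, and on every slice of the plaque — linked to co-registered T2,
pre-contrast T1 and post-contrast T1 volumes. A synthetic-data module
builds complete lesion stacks and cohort tables with known ground truth,
so every stage is testable without patient data.

## The quantities

With MLA the minimum lumen area, VA_s the outer-wall (vessel) area at the
most-stenotic section, D the lumen effective circular diameter
2·√(area/π), and subscript *n* denoting the mean of the proximal and
distal reference sites:

- stenosis (%) = (D_n − D_s)/D_n × 100
- plaque burden (%) = (1 − MLA/VA_s) × 100
- remodeling ratio (%) = VA_s/VA_n × 100
- eccentricity index (%) = (Wall_max − Wall_min)/Wall_max × 100, where the
  wall thickness at each resampled lumen-boundary point is its shortest
  distance to the outer-wall polygon
- enhancement ratio (%) = [(S_plaque,post/S_gm,post) /
  (S_plaque,pre/S_gm,pre) − 1] × 100, normalized to gray-matter signal and
  computed both at the stenotic site and over the whole plaque
- plaque volume (mm³) = Σ_slices (outer area − lumen area) × slice spacing
- intraplaque hemorrhage: any sufficiently large connected wall region
  whose pre-contrast T1 signal exceeds 150% of adjacent muscle
- first-order histogram features of the stenotic-site wall ROI on
  pre-contrast T1: mean, median, SD, min, max, Shannon entropy (bits, 256
  equal-width bins) and the coefficient of variation CV = SD/mean

Statistics follow the field's conventions: Shapiro-Wilk routes each
two-group comparison to Welch's *t* or Mann-Whitney *U*; 2×2 tables use
Yates-corrected χ² (Fisher exact when an expected count is < 5); variables
passing the univariate screen (p < 0.05) enter a multivariable logistic
model reported as Wald odds ratios with 95% CIs; discrimination is
summarized by empirical ROC curves with DeLong AUC confidence intervals
and the Youden operating point, including a combined index from the joint
model's linear predictor; reader agreement uses ICC(A,1) and Bland-Altman
limits of agreement.

## Worked example

```python
import plaquemorph as pm

# a noise-free synthetic plaque with known construction ground truth
params = pm.SyntheticPlaqueParams(noise_sd=0.0)   # 20% stenosis, 1.2 mm crescent
stack, truth = pm.generate_plaque_stack(params, seed=11)
m = pm.measure_plaque(stack)
print(m.plaque_burden_pct, m.plaque_volume, m.eccentricity_index_pct)
# 67.211 17.767 79.987     (construction truth: 67.216, 17.783, 80.000)

# a 111 + 39 synthetic cohort drawn from the calibrated group distributions
cohort = pm.generate_cohort(seed=7)
report = pm.run_full_analysis(cohort)
roc = report.rocs["plaque_volume"]
print(round(roc.auc, 3), round(roc.auc_ci_low, 3), round(roc.auc_ci_high, 3))
# 0.963 0.938 0.988
```

The measured indices agree with the generator's analytic ground truth to
a fraction of a percent (the residual is polygon discretization and the
0.5 mm voxel grid). In the cohort example, plaque volume discriminates
culprit from non-culprit plaques with AUC ≈ 0.96 — plaque volume and the
whole-plaque enhancement ratio are the two features that stay significant
in the joint logistic model, and their combination raises the AUC
further, mirroring the behaviour reported for real cohorts.

The same pipeline runs from the shell:

```bash
plaquemorph simulate --seed 1 --out run/           # cohort + image stacks
plaquemorph measure  --stacks run/stacks --out run/measurements.csv
plaquemorph analyze  --cohort run/cohort.csv --seed 1 --out run/report
```

`measure` is fully deterministic; all randomness lives in `simulate` (and
in the seeded subsampling of `analyze`'s agreement sub-study). Every
output directory carries a manifest with the seed, configuration and
input hashes.

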