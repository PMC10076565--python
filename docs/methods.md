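# Methods

This note records the modelling and numerical choices behind plaquemorph:
what each stage computes, what the synthetic data emulate (and what they do
not), and where the design was genuinely open.

## Geometry

A plaque is represented by closed simple polygons (lumen and outer wall)
per cross-section, in millimetre coordinates. Contours are normalized to
counter-clockwise orientation on load; self-intersecting or zero-area
polygons are rejected at construction, and each cross-section validates
that every lumen vertex lies inside the outer-wall polygon.

**Areas** are shoelace areas of the polygons; **effective diameters** are
circular-equivalent diameters 2·√(area/π) of the lumen areas. Diameters
could equally be defined on the outer wall; the lumen was chosen because
stenosis is a luminal quantity and the minimum lumen area is already the
area-based primitive.

**Wall thickness** is measured from the lumen outward: the lumen boundary
is resampled to `n_samples` (default 256) points equally spaced by arc
length, and each point's thickness is its shortest Euclidean distance to
the outer-wall polygon (edges included, not vertices only). This
point-to-polygon definition is robust for eccentric lumens, unlike rays
through a centroid, which can cross the wall obliquely. The measurement is
direction-asymmetric in general (lumen→outer ≠ outer→lumen); lumen→outer
was chosen and is not claimed to match any particular clinical software.
On smooth contours the extrema change by under 10⁻³ mm between 512 and
1024 samples.

**Rasterization** selects voxels whose centers fall inside the outer wall
and outside the lumen. Voxel (row, col) has its center at
(x, y) = (col, row) × spacing; 0-based slice indexing, 0.5 mm isotropic
default spacing. An annulus thinner than a voxel can select no centers
and is treated as an error rather than silently measuring nothing.

**Multiplanar reformation** extracts the plane through a centerline point
normal to the local tangent by trilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1). The in-plane basis is built by
Gram-Schmidt from the x-axis (or y-axis when the tangent is nearly axial),
so a straight z-axis centerline reproduces the native axial slice exactly.
Samples outside the volume use nearest-neighbour fill and set an
`out_of_bounds` flag on the returned slice.

## Morphometric indices

The index formulas are listed in the README. Conventions worth noting:

- Reference quantities (D_n, VA_n) are means of the proximal and distal
  sites.
- Negative stenosis (lumen wider than reference, i.e. compensatory
  dilation) is retained and flagged, not clipped — remodeling ratios above
  100% imply it can legitimately occur.
- Whole-plaque mean signals pool all wall voxels of all slices
  (voxel-weighted), rather than averaging per-slice means; this matches
  "whole plaque" semantics and weights thick slices accordingly.
- The intraplaque-hemorrhage rule is evaluated per connected component of
  wall voxels individually exceeding 150% of mean muscle signal, with a
  minimum component size of 3 voxels, and the inequality is strict. The
  source definition ("a region within the plaque") does not pin down the
  region; component-wise evaluation avoids diluting a focal hot spot over
  the whole wall, and the minimum size suppresses single-voxel noise.

## Histogram features

First-order features are computed on the raw intensities of the
stenotic-site wall ROI on pre-contrast T1. SD uses the n−1 denominator;
entropy is Shannon entropy in bits over 256 equal-width bins spanning the
per-ROI min–max range (the radiomics convention; it bounds entropy at 8
bits, consistent with typical reported plaque entropies of 6.5–6.6); CV is
SD/mean and is undefined for non-positive means. Binning and log base are
not standardized across the literature, so absolute entropy values are
comparable only within a fixed configuration.

## Synthetic data

The generator serves two distinct purposes.

**Geometric channel** (`generate_plaque_stack`): a straight tubular vessel
along z with an eccentric crescent-shaped wall thickening. The lumen
radius narrows toward the stenotic slice by a cosine-tapered fraction
(< 0.5 enforced — only non-stenotic plaques are admissible); the outer
radius adds a baseline wall plus a crescent whose angular profile is a
raised cosine of configurable extent. Volumes (T2, pre/post T1) are
rendered on a 0.5 mm isotropic grid with constant gray-matter and muscle
reference blocks, Gaussian intensity noise in the wall, an optional IPH
hot spot at 1.7× muscle signal, and post-contrast wall signal scaled by
the constructed enhancement factor. Ground truth for every index is
computed by dense brute-force evaluation of the continuous radius
functions (8192 angular samples; thickness via point-to-segment distances
with no shapely involvement), so the oracle is independent of the
measurement path. At zero noise, measurement recovers areas and volumes
within ~0.1% and thickness extrema within ~1%.

`sample_plaque_params` draws a study population whose parameter ranges
were set so the measured morphometric dispersions match the published
culprit-cohort spread (minimum wall thickness SD ≈ 0.16 mm vs the
reported 0.17; eccentricity index SD ≈ 9.3 vs 9.7 percentage points),
while keeping every draw non-stenotic and every wall resolvable on the
grid (baseline wall ≥ 0.3 mm ≈ 0.6 voxel).

**Statistical channel** (`generate_cohort`): per-patient tables with
continuous features drawn from truncated normals at the published group
means ± SDs (truncation at physical bounds: volume > 0, burden in
(0, 100), enhancement ratios > −100%, entropy in (0, 8)), binary
covariates from Bernoulli at the published prevalences, and NIHSS from a
truncated geometric pmf (decay 0.82 on 0–18 for culprit, 0.40 on 0–6 for
non-culprit; decays chosen so the distribution medians equal the published
3 and 0 with margin rather than sitting on a CDF knife edge). The
published non-culprit MLA entry is internally inconsistent (its SD is
implausible against the culprit value) and is excluded from the
generator's feature set. Features are independent by default; a Gaussian
copula accepts a user-supplied correlation matrix, because the combined-
ROC result depends on the volume–enhancement correlation, which is not
public. All randomness flows from one explicit seed.

What the synthetic data do **not** emulate: MRI contrast physics, bias
fields, flow artifacts, partial-volume effects, inter-feature correlations
(unless supplied), or any coupling between the geometric and statistical
channels — the cohort feature table is drawn from distributions, not
measured from rendered stacks. Passing tests therefore demonstrate that
the measurement and statistical machinery is correct under the stated
distributional conditions, not that the pipeline is robust to real
scanner data.

**Second reader** (`simulate_second_reader`): contour vertices are
displaced radially by a band-limited Gaussian field (harmonics up to order
4, exact marginal SD, default 0.05 mm) — human tracing error is smooth
along a boundary, and independent per-vertex jitter would catastrophically
bias extremal statistics such as the minimum wall thickness. Intensity
re-measurement noise is optional. Perturbations that break lumen/outer
nesting are resampled up to a retry budget. A zero-noise spec returns a
stack with bit-identical measurements.

The agreement sub-study (30 plaques, mirroring the usual reproducibility
design) compares **two independently perturbed readers**, not truth
against one noisy reader: the minimum-thickness estimate under contour
noise is biased low relative to noise-free truth, a bias that is common to
both human readers and cancels between them but would be misread as
disagreement in a truth-vs-reader comparison. Under this design all
morphometric ICCs exceed 0.75 at 0.05 mm noise; the eccentricity index
and minimum wall thickness are consistently the least reproducible
indices, as expected for quantities derived from extremal statistics.

## Statistics

- Welch's (unequal-variance) t-test rather than pooled, since group SDs
  differ up to three-fold; groups are routed to Mann-Whitney U when either
  fails Shapiro-Wilk at α = 0.05 (constant columns route nonparametric
  with a warning).
- Yates continuity correction for 2×2 χ² (this choice reproduces the
  conventional reported p-values for tables of this size); Fisher exact
  when any expected count is below 5.
- Logistic models are maximum-likelihood fits (statsmodels) with Wald ORs
  and 95% CIs. Perfect separation or a singular design falls back to a
  quasi-Newton fit so coefficients remain reportable, with CIs marked
  unbounded and the model flagged; near-duplicate predictors trigger a
  collinearity warning naming the offending pair.
- ROC curves are empirical threshold sweeps; AUC is the trapezoidal area
  (identical to pairwise concordance with ½ credit for ties, verified
  exhaustively in tests); AUC CIs use DeLong's covariance estimator; the
  operating point maximizes Youden's J with ties broken toward higher
  specificity, under the decision rule score ≥ threshold → positive.
- The combined index is the linear predictor of the joint logistic model
  over the features that remain significant in it (falling back to the
  full selected set when fewer than two do).
- `binormal_auc` provides the closed form Φ((μ₁−μ₀)/√(σ₁²+σ₀²)) used as a
  deterministic cross-check of empirical AUCs under normal score
  distributions.
- Agreement: ICC(A,1) — two-way, absolute agreement, single rater — plus
  Bland-Altman bias and 95% limits of agreement (bias ± 1.96 × SD of
  differences).
- Tests are two-sided at α = 0.05 with **no multiple-testing correction**
  (matching standard practice in this literature); raw p-values are always
  reported, and users screening ~20 variables should interpret borderline
  selections accordingly.

## Problem sizes

Default sizes were chosen so the full simulate → measure → analyze round
trip and the complete test suite run in well under a minute on one CPU:
cohorts of 111 + 39, image grids of 32×32×11 voxels at 0.5 mm, 96-vertex
contours, 256 thickness samples, a 30-plaque agreement sub-study, 2000
replicates for the type-I-error calibration, and n = 5000–20,000 draws for
the Monte-Carlo recovery checks. All are configurable.

## Known limitations

- No automatic segmentation or registration: contours are inputs and the
  weightings are assumed co-registered (contours are copied across
  sequences, as in manual workflows).
- The IPH rule and histogram binning are stated conventions, not
  validated against histopathology.
- The cohort generator reproduces first and second moments and
  prevalences, not full joint distributions; empirical AUCs for skewed
  features can differ from both the binormal closed form and published
  values.
- DeLong CIs and Wald ORs are asymptotic; with 39 subjects in the smaller
  group, small-sample coverage is approximate.
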