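# Methods

`radhet` quantifies *intra-patient inter-tumor heterogeneity*: how much the
metastatic lesions of one patient differ from each other on quantitative
imaging (radiomics) features, and how much of that heterogeneity is lost
when only a handful of lesions is delineated.  This note documents the
model, the conventions that make every number deterministic, and the design
choices taken where more than one reasonable convention exists.

## Feature extraction

The extraction pipeline follows the standard CT radiomics recipe:

1. **Resampling.** Image and segmentation are resampled to 1×1×1 mm voxels.
   Intensities use cubic B-spline interpolation; the binary mask is
   interpolated linearly and thresholded at 0.5 — B-spline overshoot on a
   binary field would create spurious voxels.  Output grids are
   corner-aligned with the input field of view, and nearest-neighbour
   extrapolation is used at the grid edge so constant fields stay constant.
   With this convention a digitized 10 mm sphere sampled at 2 mm conserves
   its volume to within ~1% after resampling.
2. **Discretization.** Fixed bin width of 10 intensity units anchored at
   the ROI minimum: `bin(x) = floor((x − min)/10) + 1`.  The anchor makes
   all texture features invariant to a global intensity shift.
3. **Feature computation.** Only the features used for heterogeneity
   profiling are computed natively — the eight segmentation-robust,
   uncorrelated features (90th percentile, large dependence emphasis, large
   dependence high gray level emphasis, dependence variance, IMC1,
   sphericity, maximum axial 2D diameter, voxel volume) plus mesh volume for
   comparison.  The full 107-entry catalog (18 first-order / 14 shape / 24
   GLCM / 16 GLRLM / 16 GLSZM / 5 NGTDM / 14 GLDM) ships as a name registry
   so externally extracted tables can be ingested and validated; computing
   all 107 natively is explicitly out of scope.

Conventions fixed once so the values are reproducible (each is verified
against an independent brute-force oracle in the test suite):

- **GLCM**: one matrix summed over the 13 unique distance-1 3D offsets,
  symmetrized, normalized by the pair count.  Entropies use log2 (the IMC1
  ratio is base-invariant).  `IMC1 = (HXY − HXY1)/max(HX, HY)`, defined as 0
  when `max(HX, HY) = 0`; `IDMN = Σ p(i,j)/(1 + (i−j)²/Ng²)`.  ROIs too
  small to form a voxel pair use the single-level conventions (IMC1 = 0,
  IDMN = 1).
- **GLDM**: dependence size `k = 1 + #{in-mask 26-neighbors with |level
  difference| ≤ α}`, α = 0.  Note a consequence: a *constant* ROI does not
  generally have zero dependence variance — boundary voxels have fewer
  neighbors than interior voxels, so k varies unless every voxel is a
  neighbor of every other (a 2×2×2 block).
- **Percentiles** interpolate linearly between order statistics.
- **Moments**: texture-matrix probabilities use plain normalization;
  first-order standard deviations use n−1.
- **Meshing**: surface meshes come from marching cubes at the 0.5 iso-level.
  The occupancy field is first smoothed with a Gaussian of 1 voxel —
  meshing the raw binary field produces 45° staircase facets that
  overestimate surface area by ~8–10% and cap the sphericity of a perfect
  digitized sphere near 0.91; with anti-aliasing a 10 mm digital sphere
  scores ≈0.997 and the approach to 1.0 is monotone in radius.  Masks too
  small to retain an interior value above the iso-level after smoothing are
  meshed raw, and one-voxel masks use the voxel cuboid directly.
- **Maximum 2D diameter (slice)** is the largest pairwise in-plane distance
  between in-mask voxel centers, maximized over axial slices.

## Robustness filtering and feature selection

Each lesion mask is eroded and dilated by a 1 mm Euclidean ball (the
7-voxel cross at 1 mm spacing).  For every feature, Lin's concordance
correlation coefficient

  CCC = 2·s_xy / (s_x² + s_y² + (μ_x − μ_y)²)   (population moments)

is computed between the original-mask and each perturbed-mask extraction,
pooled over all lesions of all patients; the feature is kept only if both
CCCs are ≥ 0.8.  Pooling cohort-wide (rather than per patient) maximizes n
and yields a single kept-set; lesions that vanish under erosion are
excluded pairwise and counted, never imputed.  Two constant, equal-mean
sequences define CCC = 1 if identical, else 0.

Kept features are clustered with average-linkage hierarchical clustering on
the distance 1 − |Pearson r|, and the dendrogram is cut at a fixed k
(default 8) — the cluster count is a visual/config choice, so no automatic
cut is attempted.  Constant features have undefined correlation and become
flagged singleton clusters.  One representative per cluster is kept: the
highest-ranked member of an interpretability preference list (volume-type
features first), else the lexicographically first member.

## Heterogeneity quantification

Two complementary views:

- **Absolute coefficient of variation**: per patient and feature,
  `CV = 100·|s/μ|` with the n−1 standard deviation, pooled to a per-patient
  mean across features.  When |μ| is numerically zero relative to the data
  scale (< 1e−12 of max |x|), the CV is flagged undefined (NaN) rather than
  reported as a huge number — features such as IMC1 or skewness can straddle
  zero, and flagging keeps pooled means finite without biasing them.
- **Pairwise-dissimilarity indexes**: features are min-max normalized over
  all lesions of the cohort (constant features map to 0), making every
  lesion vector nonnegative; the dissimilarity of two lesions is the cosine
  distance `1 − a·b/(‖a‖‖b‖)`, which is then bounded by [0, 1] exactly.
  Per patient, the **maximal tumoral divergence (MTD)** is the maximum
  pairwise dissimilarity and the **average tumoral heterogeneity (ATH)** is
  the mean over the n(n−1)/2 pairs.  Both are undefined for single-lesion
  patients.  An all-zero normalized vector (a lesion at the cohort minimum
  on every feature) is defined as maximally dissimilar (1) to any nonzero
  vector and identical (0) to another zero vector, the limit-consistent
  convention.  Cohort-level values are unweighted means over patients with
  defined indexes; this aggregation reproduces the worked reference values
  (per-patient ATH 0.39/0.21/0.21 → 0.27, MTD 0.94/0.92/0.91 → 0.92).

  Min-max (rather than z-score or raw) scaling was chosen because it is the
  convention under which the 1.0 bound is exact and attainable for features
  of arbitrary sign: two lesions with orthogonal normalized vectors reach
  MTD = 1.0 exactly.

## Subsampling simulation

Six strategies mirror common clinical delineation shortcuts: 1, 2 or 3
lesions at random; at most 2 or 3 lesions per metastatic site; and a
RECIST-1.1-like rule (2 per site, bone excluded).  Conventions:

- Features are normalized **once on the full cohort**; subsamples are drawn
  from that normalized table.  Renormalizing within each subsample would
  conflate sampling loss with rescaling.
- A patient whose subsample keeps < 2 lesions contributes an index of 0 —
  one lesion carries no pairwise information.  Dropping such patients would
  bias cohort means upward.  A consequence: ATH recovery can exceed 100%
  for lucky draws (a subsample's mean pair dissimilarity may beat the full
  mean), while MTD recovery never can (a subset maximum cannot exceed the
  set maximum) — both behaviours are asserted in the tests.
- The exhaustive ground truth is computed through the same estimator code
  path as the simulation draws, so exhaustive sampling recovers exactly
  100% and the MTD subset bound holds exactly in floating point.
- `random_k` takes the first k entries of a random permutation, so under
  common random numbers the sampled subsets are nested in k and recovery is
  pathwise monotone.
- Per strategy, 500 simulation draws yield the mean recovery and a
  2.5–97.5 percentile interval.  The recovery curve runs `random_k` for
  k = 2…15 and reports the smallest k whose mean recovery reaches 75% for
  *both* indexes.

## Cohort statistics

Per feature: a two-sided one-sample t-test of the per-patient mean CVs
against 0, and a two-sided Wilcoxon rank-sum comparison between the
oligometastatic and multimetastatic groups.  The rank-sum p is exact — the
full permutation distribution of the rank sum is enumerated for total
n ≤ 16, with midranks for ties (ties then shrink the attainable deviations,
so no continuity correction is needed) — and falls back to the tie-corrected
normal approximation for larger samples.  The significance threshold is
Bonferroni-corrected by the number of tests actually run, which is recorded
in the report rather than assumed.  Degenerate inputs use limiting
conventions: all-zero CVs give p = 1, constant nonzero CVs give p → 0.

## Synthetic data

No patient imaging is distributed, so the generators define the study
conditions everything is tested under:

- **Imaging cohorts.** A lesion is an ellipsoid whose boundary radius is
  perturbed multiplicatively by a random low-order angular field (degree-1
  plus traceless degree-2 terms — the simplest controllable deviation from
  sphericity), intersected with its largest 26-connected component.
  Intensities are white noise convolved with an isotropic Gaussian kernel
  (sd = texture correlation length, default 2 mm) and rescaled to the
  target mean/sd — the simplest field with a tunable texture scale for
  GLCM/GLDM features.  Per patient, base parameters (radius 4–9 mm,
  mean −20…80 HU, sd 8–25 HU) are drawn once and per-lesion parameters
  diverge from them by an amount scaled by a heterogeneity level in [0, 1];
  level 0 clones the parameters.  Site labels are metadata only and never
  alter intensities, so per-site sampling strategies can be tested
  independently of feature shifts.  Presets mirror the three study
  populations: an exhaustively annotated cohort (3 patients, 25–69 lesions
  each), an oligometastatic cohort (18 patients, 2–5 lesions) and a
  multimetastatic cohort (22 patients, ≥15 lesions; the generator uses
  15–25 since no upper bound is defined).  One root seed is split into
  per-patient and per-lesion streams (`SeedSequence.spawn`), so cohorts are
  bit-reproducible and stable under reordering.
- **Feature tables with analytic ground truth.** Per patient, two
  nonnegative orthonormal directions b₁, b₂ with disjoint feature support
  are drawn; lesion i gets the unit vector cos(θᵢ)b₁ + sin(θᵢ)b₂ with
  θᵢ ~ U(0, s).  The cosine dissimilarity of two lesions is exactly
  1 − cos(θᵢ − θⱼ), so the expected ATH has the closed form
  1 − 2(1 − cos s)/s², monotone in the spread s ∈ [0, π/2]; s = 0 gives
  zero heterogeneity and (θ = 0, θ = π/2) attains the MTD supremum 1.0.
- **Planted correlation clusters.** Features are scaled copies of one of 8
  latent factors plus Gaussian noise (sd 0.05), for validating that the
  clustering step recovers a known partition.

What the generators do *not* emulate: organ anatomy and lesion placement,
CT acquisition artifacts and noise spectra, scanner/protocol batch effects,
inter-observer contouring variability, and any correlation between site
label and intensity statistics.  Passing tests therefore demonstrate the
correctness and internal consistency of the computations and the qualitative
behaviour of the subsampling loss — not clinical effect sizes, which depend
on real lesion biology.

## Problem sizes and determinism

Default simulation settings (500 draws per strategy, k = 2…15 recovery
curves) match the reference analysis.  The test suite exercises the
pipeline end to end on reduced cohorts (3–8 patients, 20–50 draws) chosen
so the whole suite runs in well under a minute of simulation time while
still triggering every code path; the acceptance checks use the full 500
draws where the property being tested is distributional.  Every stochastic
stage takes an explicit seed, and a pipeline run writes a JSON manifest
(config, seed, package version, config hash) next to its outputs; two runs
with the same seed are byte-identical.

## Known limitations

- Only the 8 robust features (+ mesh volume) are computed natively;
  analyses over the full 107-feature catalog require an externally
  extracted table.
- The CCC pooling convention (cohort-wide, not per patient) and the
  min-max/cosine normalization are fixed choices among defensible
  alternatives; both are isolated behind single functions and the clustering
  metric/linkage are config-overridable.
- The RECIST-like strategy models only the "two per organ, no bone" rule,
  not size-based target-lesion eligibility.
- Recovery percentages compare cohort-level (patient-mean) indexes; a
  per-patient recovery analysis is available but not the headline output.
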