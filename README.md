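# radhet

**Radiomics-based quantification of intra-patient inter-tumor
heterogeneity, and of how much of it lesion subsampling throws away.**

In metastatic cancer, radiomics studies typically delineate only one or a
few lesions per patient.  If the lesions of one patient differ strongly on
quantitative imaging features, that shortcut discards exactly the signal —
inter-tumor intra-patient heterogeneity — that a tumor-centric predictive
model would need.  `radhet` is a library for radiomics researchers and
imaging scientists that implements the full analysis chain needed to ask
(and answer) this question on any cohort of per-lesion segmentations:

1. **Feature extraction** — resampling to 1 mm isotropic voxels (B-spline),
   fixed-bin-width discretization (width 10), and native computation of the
   eight segmentation-robust, uncorrelated features used for heterogeneity
   profiling (90th percentile, large dependence emphasis, large dependence
   high gray level emphasis, dependence variance, IMC1, sphericity, maximum
   axial 2D diameter, voxel volume), plus ingestion of externally extracted
   tables validated against the canonical 107-feature catalog.
2. **Robustness filtering** — every mask eroded/dilated by 1 mm; features
   kept only if Lin's concordance correlation coefficient with the original
   extraction is ≥ 0.8 under both perturbations:
   CCC = 2·s_xy / (s_x² + s_y² + (μ_x − μ_y)²).
3. **Feature selection** — average-linkage hierarchical clustering on
   1 − |r|, cut at k = 8 clusters, one interpretable representative each.
4. **Heterogeneity quantification** — per patient and feature the absolute
   coefficient of variation CV = 100·|s/μ|; and on min-max-normalized
   feature vectors the two cosine-dissimilarity indexes,
   **maximal tumoral divergence** MTD = max over lesion pairs of
   d(a,b) = 1 − a·b/(‖a‖‖b‖) and **average tumoral heterogeneity**
   ATH = mean over pairs — both bounded by 1.0 exactly.
5. **Subsampling simulation** — six clinical sampling shortcuts (1/2/3
   random lesions, 2/3 per metastatic site, RECIST-1.1-like) scored by the
   percentage of the exhaustive-sampling heterogeneity they recover, with
   500-draw percentile confidence intervals, plus random-k recovery curves
   (k = 2…15) and the smallest k reaching 75% recovery of both indexes.
6. **Cohort statistics** — one-sample t-tests for CV non-nullity, exact
   Wilcoxon rank-sum oligo-vs-multimetastatic comparisons, Bonferroni
   correction.

Because per-patient imaging of this kind cannot be redistributed, the
package ships first-class synthetic generators: imaging cohorts (perturbed
ellipsoid masks with textured Gaussian intensity fields, preset to the
three study populations) and feature tables with *analytically known*
expected heterogeneity, used throughout the test suite.

## Worked example

```python
import numpy as np
from radhet import (generate_feature_table, cohort_indexes,
                    simulate_strategy, standard_strategies)

# 10 multimetastatic patients, 20 lesions each, known angular spread
table = generate_feature_table(n_patients=10, n_lesions=20,
                               angular_spread=1.3, n_features=8, rng=9)
cohort, per_patient = cohort_indexes(table, normalize=False)
print(f"MTD={cohort.mtd:.3f}  ATH={cohort.ath:.3f}")

rng = np.random.default_rng(9)
for strategy in standard_strategies():
    s = simulate_strategy(table, strategy, n_sim=500, rng=rng).summary()
    print(f"{strategy.label:40s} mtd {s['mtd_mean']:5.1f}% "
          f"[{s['mtd_ci_lo']:.0f}-{s['mtd_ci_hi']:.0f}]  "
          f"ath {s['ath_mean']:5.1f}% [{s['ath_ci_lo']:.0f}-{s['ath_ci_hi']:.0f}]")
```

prints

```
MTD=0.633  ATH=0.146
1 lesions at random                      mtd   0.0% [0-0]  ath   0.0% [0-0]
2 lesions at random                      mtd  23.8% [9-40]  ath 101.3% [38-172]
3 lesions at random                      mtd  41.6% [25-61]  ath 100.4% [58-146]
2 lesions per site at random             mtd  78.4% [68-88]  ath 100.4% [86-115]
3 lesions per site at random             mtd  88.0% [81-95]  ath 101.9% [91-112]
RECIST-like (2 per site, no bone)        mtd  77.2% [66-87]  ath 104.9% [89-122]
```

Reading: one random lesion recovers 0% of both indexes (a single lesion has
no pairwise dissimilarity); two or three random lesions systematically miss
the worst-divergence pair (MTD 24–42%); per-site strategies do better only
because they sample many lesions on this cohort.  ATH hovers near 100% here
because this synthetic construction spreads lesions evenly — on cohorts
with outlier lesions ATH is underestimated too.  A subsample can overshoot
100% on ATH (a lucky pair can beat the full-cohort mean) but never on MTD:
a subset maximum cannot exceed the set maximum.

The `examples/` directory walks each capability end to end
(`01_simulate_cohort.py` … `06_full_pipeline.py`), and the `radhet` CLI
(`simulate-cohort`, `extract`, `robustness`, `select-features`,
`heterogeneity`, `sample-sim`, `recovery-curve`, `stats`, `run-all`) wraps
the same functions for shell use.  See `docs/methods.md` for the exact
conventions and the synthetic-data model.

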