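# gaitstrat

Data-driven stratification of heterogeneous gait patterns.

People with incomplete spinal cord injury (iSCI) walk in very different
ways: depending on which sensorimotor functions are preserved, gait ranges
from near-normal to severely compromised. Summary scores (manual muscle
testing, WISCI II) and single kinematic parameters do not capture this
diversity. `gaitstrat` implements a pipeline that stratifies a cohort's gait
cycles into data-driven subgroups directly from multidimensional joint-angle
time series, and then characterizes each subgroup both clinically and
through an explainable classifier.

## Method

The unit of analysis is one **gait cycle**: nine joint/segment angle
channels (pelvis tilt/obliquity/rotation, hip flexion/adduction/rotation,
knee flexion, ankle dorsiflexion, foot progression) sampled at 100 Hz, kept
on its raw time base so that cycle-duration differences remain informative.
Sides are treated independently; the weaker leg is identified from summed
MMT scores with hip→knee→ankle→hallux tie-breaking.

1. **Normalization.** Each channel *m* is Z-normalized with one global mean
   and standard deviation pooled over all impaired cycles,
   g̃ᵐ = (gᵐ − μᵐ)/σᵐ, removing the amplitude bias toward sagittal-plane
   channels. Control data never enter the statistics.
2. **Dissimilarity.** Dependent dynamic time warping (DTW_D) aligns all nine
   channels along a single warping path with local cost
   c(i,j) = Σₘ (wₘ·(aᵐᵢ − bᵐⱼ))², pelvis channels at half the weight of the
   distal channels, inside a Sakoe–Chiba band of half the cycle length
   (r = 0.5). The distance is the raw accumulated cost — no square root, no
   path-length normalization.
3. **Clustering.** Ward-like hierarchical agglomeration on the dissimilarity
   matrix: each merge minimizes the increase of pseudo within-cluster
   inertia I(C) = (1/n_C)·Σ_{i<j∈C} d²ᵢⱼ, maintained with the Lance–Williams
   recurrence. The dendrogram is cut at a chosen height or cluster count;
   clusters get non-ordinal colour names by descending size.
4. **Clinical characterization.** Each side is represented by the median of
   its cycles; Kruskal–Wallis with Dunn/Bonferroni post-hocs compares MMT
   scores, WISCI II and temporospatial parameters across clusters,
   chi-squared compares categorical descriptives, and Spearman's rank
   correlation probes feature–performance couplings.
5. **Discrimination.** For each cluster, a binary problem (cluster vs
   control) over 27 per-cycle kinematic features is rebalanced with SMOTE,
   grid-searched over a 54-configuration random-forest grid with 10-fold
   stratified cross-validation, and explained with path-dependent TreeSHAP
   attributions ranked by mean |SHAP|.

A synthetic-cohort generator with six planted gait archetypes (plus a
control archetype) stands in for motion-capture data, so the whole pipeline
is testable end to end; see `docs/methods.md` for the generative model.

## Worked example

```python
from gaitstrat import (
    CohortConfig, generate_cohort, fit_normalization, pairwise_matrix,
    hac_wardlike, cut_k, side_assignments, planted_correlation_check,
)

cohort = generate_cohort(CohortConfig(seed=1))   # 28 iSCI + 21 control subjects
isci = cohort.isci_cycles                        # 280 impaired cycles
norm = fit_normalization(isci)
matrix = pairwise_matrix(isci, norm)             # 280x280 DTW_D distances
assignment = cut_k(hac_wardlike(matrix), 6)
sides = side_assignments(assignment, isci)

print(f"{matrix.n} cycles clustered into {assignment.n_clusters} groups")
for label in range(assignment.n_clusters):
    n = len(assignment.members(label))
    print(f"  {assignment.names[label]:7s} {n:3d} cycles ({100*n/matrix.n:.0f}%)")
print(f"sides with all five cycles in one cluster: {sides.consistent.mean():.0%}")
print(f"plantarflexion-at-toe-off vs walking speed: "
      f"rho = {planted_correlation_check(cohort):.2f}")
```

prints

```
280 cycles clustered into 6 groups
  blue     80 cycles (29%)
  pink     65 cycles (23%)
  violet   50 cycles (18%)
  green    45 cycles (16%)
  orange   25 cycles (9%)
  cactus   15 cycles (5%)
sides with all five cycles in one cluster: 100%
plantarflexion-at-toe-off vs walking speed: rho = 0.80
```

The six recovered groups match the planted archetypes (five cycles of each
side co-cluster), and the side-median rank correlation between push-off
plantarflexion and walking speed recovers the coupling planted by the
generator.

The same stages are available from the shell:

```bash
gaitstrat simulate --n-subjects 28 --n-controls 21 --seed 1 --out data/
gaitstrat dtw-matrix --cycles data/cycles.csv --out matrix.csv
gaitstrat cluster --matrix matrix.csv --k 6 --out run/
gaitstrat run-all --out run/ --seed 1          # everything at once
gaitstrat ablate --drop-to 4                   # subsampling stability
```

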