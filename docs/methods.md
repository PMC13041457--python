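# Methods

This note documents the models, numerical conventions and design choices
behind `gaitstrat`, and what the synthetic cohort generator does and does
not emulate.

## Data model

A gait cycle spans initial contact to the next ipsilateral initial contact
and carries nine angle channels in degrees at a fixed sampling rate
(default 100 Hz). Sign conventions are positive for pelvis anterior tilt,
pelvis upward obliquity, pelvis internal rotation, hip flexion, hip
adduction, hip internal rotation, knee flexion, ankle dorsiflexion and foot
internal progression. Toe-off is supplied as input metadata (instrumented
walkways provide gait events; kinematic event detection is out of scope),
and phases are half-open, 0-based: stance `[0, toe_off)`, swing
`[toe_off, T)`. Cycles are **not** resampled to percent-gait: preserving
durations is a deliberate property of the dissimilarity measure.

MMT grades quantize as base digit ±0.5 for `+`/`-` refinements; results
outside [0, 5] are rejected. The weaker leg is the side with the lower
summed score; ties fall through joint sums in the order hip, knee, ankle,
hallux, and a full tie designates the right side.

## Z-normalization

One global (μᵐ, σᵐ) per channel is pooled over *every sample* of *every
impaired cycle* — longer cycles therefore weigh more. The alternative
(mean of per-cycle means) would weight cycles equally; sample pooling was
chosen because the normalization exists to equalize channel scales, which
is a property of the pooled sample distribution. σ uses the population
(divide-by-N) convention; with thousands of pooled samples the difference
from the sample convention is far below any decision threshold, but the
convention is fixed for exact reproducibility. A constant channel (σ = 0)
is an error rather than an epsilon-fudge: a constant anatomical angle
indicates degenerate input. Control cycles never contribute to the
statistics and are never clustered; they enter only the feature stage, in
raw degrees.

## Dependent DTW

All nine channels share one warping path (the channels of one limb are
tightly coupled, so independent per-channel warping would destroy their
phase relationships). Local cost is squared Euclidean on weighted samples,
with weights *inside* the square — weighting the series, not per-channel
DTW distances, which would be independent DTW. Pelvis channels get weight
0.5 against 1.0 for hip/knee/ankle/foot, damping the influence of pelvis
kinematics shared by both sides. The step pattern is the symmetric
{(1,0),(0,1),(1,1)} set with D(0,0) = c(0,0), and the returned distance is
the raw accumulated cost: no square root and no path-length normalization,
so longer and more temporally mismatched cycles are genuinely farther
apart.

The Sakoe–Chiba constraint is expressed in cross-product form,
`|i·(M−1) − j·(N−1)| ≤ r·(N−1)·(M−1)` with r = 0.5 by default, which is
symmetric in the two series and slope-corrected for unequal lengths (the
first sample of one series can match at most the first half of the other).
The half-width is floored at `max(N−1, M−1)/2` — the smallest value for
which the corridor of admissible lattice cells is guaranteed connected (the
Bresenham line bound). Without the floor, extreme length ratios (e.g. 2 vs
11 samples at r = 0.25) admit no monotone path at all; for realistic cycle
lengths the floor is inactive. Ties among DP predecessors cannot affect the
distance and no path is materialized. Pairwise matrices are computed for
i < j and mirrored, with an exactly zero diagonal; the inner loop computes
local costs from raw differences (not an inner-product expansion) so that
identical cycles yield exactly zero.

## Ward-like clustering

Classical Ward minimizes the variance increase of Euclidean coordinates;
on a DTW dissimilarity matrix no coordinates exist, so the pseudo-inertia
generalization is used: `I(C) = (1/n_C)·Σ_{i<j∈C} d²(i,j)`. The merge cost
S(A,B) = I(A∪B) − I(A) − I(B) initializes to d²/2 for singleton pairs and
updates by the Lance–Williams recurrence with Ward coefficients

    S(A∪B, K) = [(n_A+n_K)·S(A,K) + (n_B+n_K)·S(B,K) − n_K·S(A,B)]
                / (n_A+n_B+n_K).

Merge heights are these pseudo-inertia increases directly, so the
dendrogram's vertical axis is interpretable as inertia on the DTW scale;
on Euclidean inputs the heights equal classical Ward's h²/2 (verified
against both scipy and a from-scratch greedy inertia oracle in the tests).
The DTW distance enters squared throughout. Merge-cost ties break by the
lexicographically smallest cluster-id pair for reproducibility. Heights
from valid dissimilarities are monotone (Ward is reducible); a
non-monotone sequence is logged, not fatal.

Cutting is by height threshold or exact cluster count; threshold selection
is intentionally manual/config-driven (cluster analysis is exploratory and
the cut is context-dependent), with a largest-relative-gap heuristic
provided as a clearly-labeled extension for unattended runs. Cluster
display names are a size-ranked colour palette — the names are non-ordinal
labels, nothing more.

## Feature catalogue

27 per-cycle features, computed on raw degrees (never normalized data):
ten named clinical discriminators (mean hip rotation in stance and swing,
minimum stance knee flexion, swing knee-flexion range, mean stance foot
progression, full-cycle ankle dorsiflexion range, ankle plantarflexion at
toe-off, minimum stance hip flexion, maximum stance dorsiflexion, and the
time of maximum hip flexion in swing) padded with systematic per-channel
stance means, swing means and full-cycle ranges to exactly 27. Timing
features are absolute seconds from cycle start, so duration pathology is
visible in them. Only the plantarflexion-at-toe-off feature flips sign
(plantarflexion positive) for clinical readability. The registry is a YAML
file; users can substitute their own catalogue (lengths other than 27 are
accepted with a warning). Whether "dorsiflexion range" should be full-cycle
or swing-only is genuinely ambiguous clinically; full-cycle is the default
and a swing-only definition is one registry line away.

## Discrimination stage

One binary model per cluster: its cycles (label 1) against all control
cycles (label 0). SMOTE synthesizes minority rows as x + u·(x_nn − x) with
u ~ U(0,1) and x_nn among the k = 5 nearest minority neighbours, exactly
balancing the classes while preserving originals verbatim. The default
pipeline applies SMOTE once, before cross-validation — faithful to common
practice but leaky, since synthetic neighbours of a training row can land
in validation folds; `safe_resampling=True` applies SMOTE inside each
training fold instead. Both modes are first-class because the question of
which a given historical analysis used often cannot be settled.

The grid is 3 tree counts × 2 max-features rules × 3 depths × 3 split
criteria = 54 configurations, each scored by 10-fold stratified CV
accuracy; ties resolve to the first configuration in deterministic grid
order, and one pipeline seed drives SMOTE, fold shuffling and forest
bootstraps.

Attributions use an in-package implementation of path-dependent TreeSHAP:
Shapley values under the value function in which features absent from a
coalition are integrated out by descending both children of a split
weighted by training cover. Attributions are computed in positive-class
probability space and satisfy local accuracy (base value plus attribution
sum equals the predicted probability, to ~1e-12 per tree); the
implementation is validated against a brute-force exact-Shapley oracle on
small forests. Global impact is the mean absolute attribution per feature.

## Statistics

Sides are the unit of analysis: each (subject, side) contributes the
median over its cycles, and those medians are treated as independent.
Kruskal–Wallis uses midranks with tie correction and the χ² reference
(identical values across all groups give H = 0, p = 1 — no evidence, not
an error). Post-hocs are Dunn's rank-based z-tests with Bonferroni
correction, adjusted p = min(1, p·m) over all C(g,2) pairs (pairwise
Mann–Whitney is available as an alternative since "pairwise post-hoc" is
underspecified in common reporting). Chi-squared is Pearson's without
continuity correction and requires positive margins. Spearman uses
midranks and the t-approximation p-value, reported as r_s(df = n−2).
Cluster reports state n both as sides and as cycles, since either
convention appears in practice.

## Synthetic cohort generator

The generator exists so that every stage has a ground truth. Per channel,
a control template is a low-order harmonic series (offset + 2–3
sine/cosine terms) least-squares fitted through canonical gait key points;
the ankle additionally carries a narrow Gaussian pre-swing plantarflexion
burst (depth 20°, width 0.06 cycle) — one non-harmonic term, kept because
burst depth is the natural handle for the reduced-push-off deviation that
several archetypes share. Six impaired archetypes deviate via per-channel
offsets and amplitude scalings, a circular hip-curve delay, burst
attenuation, and longer cycle durations:

| archetype | portrait | duration (s) |
|---|---|---|
| green  | hip internal-rotation offset, slightly flexed stance knee | 1.08 |
| pink   | mildly reduced swing knee/ankle excursions, internally rotated foot | 1.14 |
| violet | no hip extension, excess stance dorsiflexion, weak push-off | 1.35 |
| blue   | reduced dorsiflexion range, delayed hip-flexion peak, weak push-off | 1.30 |
| orange | severely reduced swing knee range and push-off, slow | 1.75 |
| cactus | persistent knee flexion, strongly delayed hip peak, very long cycles | 3.4 |

Within a side, cycles share side-level jitter (offsets ~N(0, 1.2°),
amplitude ~N(1, 0.04), burst-depth ~N(0, 2°)) and differ by low-pass
filtered Gaussian channel noise (1.5° SD, 6 Hz cutoff), a random monotone
time warp (PCHIP through jittered knots, max deviation 0.04), and
duration jitter scaled by the warp strength — so zero noise and zero warp
make a side's cycles bit-identical. The default 28-subject layout plants
side counts of 16/13/10/9/5/3 per archetype (280 cycles at five per side),
including seven asymmetric subjects whose two sides carry different
archetypes. Walking speed and step length follow
`a_archetype + b·(plantarflexion at toe-off) + ε`; the intercepts and
noise were calibrated once, by simulation, so that the pooled side-median
Spearman correlation between push-off plantarflexion and speed lands near
0.75 (observed 0.79 ± 0.03 over 20 seeds at 100 sides) and so that cutting
the dendrogram at six recovers the planted archetypes with ARI ≥ 0.94
across seeds. Clinical covariates (MMT grade distributions, WISCI II,
sex, aids, spasticity, injury levels) are sampled per archetype, with
subject-level fields drawn from the more severe of a subject's two side
archetypes.

What the generator does **not** emulate: real normative kinematic curves
(the templates are qualitative), marker noise and soft-tissue artifact,
kinetic quantities, step-to-step autocorrelation beyond shared side
parameters, or any real cohort's reported medians. Passing tests therefore
demonstrate that the pipeline recovers structure *of the planted kind* at
realistic scale and noise — they are not evidence about any specific
clinical population.

## Numerical choices and problem sizes

- DTW dynamic programs run in a numba-compiled kernel; a 280-cycle matrix
  (39 060 pairs of ~100–360-sample cycles) takes a few seconds on one core.
- Routine test and driver runs use reduced problem sizes (6–12 subjects,
  a 4-configuration forest grid); the acceptance suite runs the full
  54-configuration grid and the 280-cycle cohort.
- The ablation driver drops the highest-indexed cycles per side
  (deterministic) by default; random subsampling sits behind a flag.
  Cluster labels between the full and subsampled runs are matched by
  greedy maximal side overlap before agreement is counted.
- All randomness flows from a single integer seed per run; pipeline runs
  write a manifest with config hash and per-output content hashes, and
  reruns are bit-identical.

## Known limitations

- The Ward-like variant implemented is the standard Lance–Williams
  generalization on squared dissimilarities with pseudo-inertia heights;
  other weighting conventions exist and would shift heights (not merges).
- Pre-CV SMOTE (the replication-faithful default) inflates CV accuracy on
  correlated folds; use `safe_resampling` when accuracy estimates matter.
- Path-dependent TreeSHAP attributions depend on each tree's training
  cover and are not the interventional variant.
- The padding portion of the 27-feature catalogue is a documented default,
  not a clinically canonical list; swap the registry file to change it.
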