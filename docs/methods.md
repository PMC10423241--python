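# Methods

## Problem and data model

The package stratifies a case–control cohort described by a participants ×
variables table. Each variable carries metadata: a biopsychosocial domain
(nervous system, spinal tissue, psychosocial, or other), declared scale
bounds, and a direction-of-benefit flag. Cases are assumed to be a mixture
of latent sub-groups; controls anchor both the normalisation and the
naming of the "normal" sub-group. Missing cells are allowed and handled
pairwise-complete for correlations and listwise-complete for clustering
and classification (the number of dropped rows is warned about); the
reference study design this mirrors is a pilot of 21 cases and 21 matched
controls, where missingness policy is an implementation decision, not an
inference about the source data.

## Normalisation

All multivariate stages run on min–max scaled data: v' = (v − min)/(max −
min) with the min/max taken over a reference row set (default: all
participants, so case and control scales stay comparable across stages;
cases-only is available). The parameters are stored, reused downstream
without re-fitting, and invertible to 1e-9. Values for rows outside the
reference set may leave [0, 1] and are flagged rather than clipped.

## Screening (case vs control)

Welch's unequal-variance t-test per variable (pooled-variance optional;
the classical description "independent t-tests" does not fix the choice,
and Welch is the safer default at unequal group spreads). Selection is
unadjusted p < α (default 0.05); Benjamini–Hochberg q-values are computed
by an in-package step-up implementation and reported for context only —
a pilot-scale screen deliberately retains pre-FDR hits. Candidates then
pass a Pearson collinearity filter: for any pair with |r| > 0.8
(absolute value — a negative duplicate is equally redundant) the member
with the larger univariate p is dropped, ties dropping the later column;
analyst-forced removals are recorded explicitly via `force_remove`.

## Feature ranking

*Supervised context:* a 500-tree random forest (√p feature subsampling)
with permutation importance (50 repeats, fixed seed) quantifies how much
each variable separates cases from controls. It informs reporting and
forced removals but does not gate the unsupervised steps.

*Unsupervised ranking (cases only):* the Laplacian score. A symmetric
k-nearest-neighbour graph (k = 5) over cases gets heat-kernel weights
exp(−d²/t) with bandwidth t defaulting to the mean pairwise squared
Euclidean distance on the unit-scaled candidates. With degree matrix D
and Laplacian L = D − S, each feature is D-demeaned and scored
L(f) = f̃ᵀLf̃ / f̃ᵀDf̃. Small scores mean the feature varies smoothly over
the graph while retaining global spread — exactly the features carrying
the geometry along which cases split — so ranking sorts ascending. A
feature constant across cases has no local structure to preserve and is
assigned +∞ (least informative).

## Cluster-validity scan

Features enter in ranked order; at each feature count and each k in the
configured range (default 2–6, bounded by expecting ≥3 members per
cluster at n = 21), k-means (10 restarts, fixed seed) partitions are
scored by Calinski–Harabasz, Davies–Bouldin and silhouette.

Raw validity indices are not comparable across feature counts: any
one-dimensional sample partitions "cleanly" (we measured silhouettes near
0.87 on structureless 1-D data), discrete marginals reward large k with
stripe artefacts, and added dimensions deflate all three indices even
when they carry signal. Each index is therefore referenced against a
small permutation null — the same statistic on copies of the data with
every column independently permuted (sorted before permuting, so the
null draws do not depend on row order), which destroys the joint cluster
structure while preserving every marginal. The working quantity is the
gap: real − null mean for CH and silhouette, null mean − real for DB.
The scan starts at two features (a univariate partition is thresholding,
not clustering), a count is "better" when at least 2 of the 3 gaps
improve at their own best k, and scanning stops at the first count that
is not better (a global-best mode is available). k is the silhouette-gap
maximiser at the selected count, ties to the smaller k. A selection whose
silhouette gap stays below 0.25 is flagged as not confident. In
simulation this null-referenced scan recovers a planted two-feature /
two-cluster structure in 100% of seeds where the raw-index variant
recovered ~17%, and raw indices remain recorded in the grid for
inspection.

## Fuzzy c-means

Standard alternating optimisation of J = Σᵢ Σ_c u_ic^m ‖xᵢ − v_c‖² with
fuzzifier m = 2, membership update u_ic ∝ (1/d²ᵢc)^{1/(m−1)} row-normalised,
centroid update v_c = Σ u^m x / Σ u^m; squared distances are floored at
1e-12 so coincident points stay defined. Convergence is a maximum
centroid shift below 1e-5 (cap 1000 iterations; non-convergence warns and
reports the final objective, it is not an error). The best of 20 random
starts by final objective is kept, and cluster ids are renumbered by
descending hard-cluster size (ties by first centroid coordinate) so runs
are reproducible. Reported metrics: per-cluster mean member–centroid
distance and mean pairwise centroid distance on the unit scale,
silhouette over hard labels (singleton clusters contribute 0 for their
point, with a warning), and a density contrast
log10(mean within-cluster variance / between-centroid variance) — an
explicit stand-in for the "discrimination value" style of cluster-density
scalar, whose original formula is not fully specified in the literature
this mirrors; it is config-pluggable and more negative means denser,
better-separated clusters.

## Classifiability benchmark

Four multi-class classifiers — RBF-kernel SVM (C = 1, one-vs-one),
Gaussian naive Bayes, kNN (k = 5, Euclidean), 500-tree random forest —
are trained on identical stratified 80/20 holdout splits over 30 runs
(run seeds derived from one master seed). Stratification is required, not
cosmetic: with a 5-member sub-group an unstratified 20% test set would
often contain no minority cases at all. Error is the misclassified test
fraction; each classifier's mean error carries a t-interval across runs,
truncated to [0, 1]. The cases-plus-controls setting adds the control
participants as one extra class over the same features.

## Post-hoc characterisation

One-way ANOVA per variable across control/sub-group(s) with Tukey-HSD
adjusted pairwise p-values (statsmodels); with two groups this reduces
exactly to the pooled t-test. Pearson correlations between the
cluster-driving variables and pain intensity / disability are computed
within cases only (controls lack those outcomes) with Fisher-z 95%
intervals. Chi-square contrasts run without continuity correction by
default (the group tables here are typically larger than 2×2); a
correction flag exists.

## Sub-domain profiles

Ranking → scan → clustering → benchmark re-run within one domain's
screening survivors; a domain with fewer than two survivors is skipped
with a recorded reason. Clusters are named against the control profile:
the cluster whose centroid is nearest the control means on the clustering
features is "normal"; every other cluster is named by its deviating
features (|centroid − control mean| ≥ 0.15 on the unit scale) with a
high/low direction. Per-participant non-"normal" labels are concatenated
in the fixed order psychosocial → spinal → nervous into a combined
profile; participants normal everywhere get an empty label. When a
many-cluster sub-domain solution leaves a class too small for a
stratified holdout, the benchmark for that domain is skipped with a
warning rather than failing the analysis.

## Synthetic cohort

Per latent group (21 controls; 16 + 5 case sub-groups) values are drawn
from a multivariate normal with the published group means and SDs for the
ten discriminating variables (four PROMIS distress scores, central
sensitisation inventory, satisfaction in social roles, maximal extension
strength, lumbar pressure-pain threshold, lumbar disc T2, 12-month
pain-site count), clipped to each variable's declared scale (warning if
over 5% of draws clip) and rounded for count variables. Ten nuisance
variables per domain (mean 0.5, SD 0.15 on a 0–1 scale, identical across
groups) give the screening step something to reject. Within-group
correlations default to zero — the reference statistics do not constrain
them — with a configuration hook for correlated draws (positive
definiteness is validated).

What the generator does *not* emulate: within-group correlation among
questionnaire scores (real PROMIS scales correlate strongly), skewness
and floor/ceiling pile-ups of questionnaire data, missingness, and
matching structure between cases and controls. Passing recovery tests on
this generator therefore establishes that the pipeline can find the
planted mean-shift structure at realistic sample sizes and noise — not
that it would find the same sub-groups in any real cohort.

## Recovery properties and a known power limit

On the default synthetic cohort the clustering chain (ranking → scan →
fuzzy c-means over all variables) selects two clusters and recovers the
hidden 16/5 labels (adjusted Rand > 0.9) in ≈96% of seeds
(`analysis/04_recovery_surface.py`). With the screening gate in front —
the faithful full pipeline — recovery drops to ≈60%: at these group
means and SDs the expected case–control Welch p for each of the four
discriminating psychosocial variables sits right at ~0.04 (the small
severe sub-group inflates the pooled case SD), so each survives the
α = 0.05 screen with probability only ~0.5–0.85, and losing two or more
of them degrades the downstream clustering. This is a statistical power
property of the design (n = 21 + 21 with a 5-member latent sub-group and
uncorrelated features), not an implementation artefact; with correlated
psychosocial features or larger n the gap closes. The recovery-surface
script reports both numbers so the cost of the screening gate is visible.

## Numerical and policy choices

- Distances are Euclidean on unit-scaled features throughout.
- All stochastic stages (generator, k-means restarts, fuzzy c-means
  starts, permutation nulls, forest fits, holdout splits) consume seeds
  derived from a single master seed; identical configuration reproduces
  every output bit for bit, and the run manifest records config, seed and
  an input-table hash.
- Degenerate inputs fail loudly with typed errors (constant variable at
  normalisation, zero-range scales, single-class labels, k out of range)
  except where the analysis can meaningfully continue (constant variable
  in post-hoc tables: flagged; non-convergent fuzzy c-means: warned).
- T2 fitting uses unweighted least squares on log intensity, per-slice
  fits averaged afterwards when multiple slices are supplied; weighting
  schemes and pre-fit pooling are deliberate non-goals.

## Limitations

The pipeline inherits the pilot design's caveats: no external validation,
calibration, stability assessment or net-benefit analysis is attempted;
cluster counts chosen at n = 21 cases are fragile, and the not-confident
flag on the validity scan should be taken seriously; the density-contrast
metric is an interpretation, not a reproduction, of the discrimination
value reported alongside silhouette in the literature this follows.
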