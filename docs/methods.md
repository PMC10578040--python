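# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic cohorts do and do not show.

## Enrichment engine

The per-sample, per-module enrichment score is a weighted
Kolmogorov–Smirnov-like random walk over within-sample gene ranks.

*Expression statistic.* Two kernels re-express each gene relative to its
cross-sample distribution. The Gaussian kernel uses
ẑᵢⱼ = (1/n) Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ) with per-gene bandwidth hᵢ = sᵢ/4 (sample
SD, ddof = 1), floored at ε = 1e−12 for constant genes; it needs ≥ 3
samples. The ECDF kernel uses the fraction of samples ≤ xᵢⱼ and depends
only on within-gene ranks, which makes scores invariant to any strictly
monotone transform of the data (tested). The kernel is a per-dataset
choice; the default is Gaussian for log2-scale intensity data.

*Ranking and walk.* Genes are ordered by decreasing statistic; ties break
deterministically by (statistic desc, gene id asc) so results are
reproducible across platforms. The rank weight |p/2 − r + ½| is largest at
both extremes of the list; τ (default 1) exponentiates the weights. The
walk increments by normalized in-set weight and decrements by 1/(p − m);
the score is the largest positive plus largest negative deviation
(max-difference convention), which keeps scores in [−1, 1] without
clamping. Degenerate weights (single-gene universe) are floored at ε.
Genes absent from a matrix are dropped from modules with a logged count;
modules falling below `min_set_size` (or equal to the whole universe) are
dropped and recorded in provenance, not scored.

The test suite holds an independent, deliberately literal O(p²)
re-enumeration of the walk; the vectorized engine must agree with it to
1e−12 on randomized instances, and a 10,000-draw randomized simulation
checks the score range bound.

## Gene-level filtering and I/O

Genes with zero across-sample IQR are removed before scoring; quantiles
use linear interpolation (the common default; the convention matters only
for the strict-positivity test and is fixed here). Duplicate gene or
sample identifiers are errors, never averaged: silent merging changes
within-sample ranks and hence every downstream score. Supported formats
are plain delimited matrices (header row = sample ids), GCT 1.2/1.3, GMT
gene sets, and delimited metadata tables keyed by `sample_id`.

## Feature-panel derivation

Redundant features are culled greedily: walking the panel in order, a
feature correlated above r = 0.9 (Pearson) with any already-kept feature
is dropped, so of a correlated chain only the first survives and the
result is deterministic in panel order. Class-imbalanced binary contrasts
are handled by balanced folds: every fold holds all minority samples plus
an equally sized without-replacement majority subsample, split 70/30
train/validation *stratified by class* (tiny folds would otherwise risk
single-class validation sets). Feature importances (random-forest Gini and
linear-SVM permutation importance) are averaged over folds — mean, not
median — and the union of the per-cohort, per-algorithm top-20 lists forms
the panel; manually re-added features are flagged as such.

## Endotype discovery and consensus

Per-dataset clustering is k-means++ with up to 300 Lloyd iterations and
best-of-restarts by inertia (the library default is 5000 restarts, the
value used at full scale; tests and the bundled pipeline use 100–200,
which is ample at the synthetic problem sizes). For choosing k, inertia
and mean silhouette are reported over the scanned range, with the elbow
formalized as the maximum perpendicular distance to the chord of the
normalized inertia curve. The *selection policy* is the largest k whose
silhouette is within 5% of the maximum. Rationale: on cluster geometries
where adjacent subsets are close, the silhouette argmax systematically
under-selects by merging the closest pair; an over-split cluster is
self-correcting downstream (its centroids merge back in the consensus
step) whereas an under-split one loses an endotype irrecoverably.

Consensus across datasets operates on cluster mean-score profiles:
complete-linkage agglomeration on Euclidean distances, cut at height 1.8.
Cosine similarity (> 0.7 considered highly similar) is used for profile
*matching* and relabeling, Euclidean distance for clustering and
centroid transfer — mirroring the split use of the two metrics in the
field. Matching is greedy best-pair rather than optimal assignment, which
keeps the similarity tables interpretable; ties in relabeling break by
reference order, and sub-threshold matches are flagged but still mapped.
Final endotypes are lettered by increasing mean signed enrichment, which
tracks the breadth of activation (relatively unenriched modules score
negative).

## Classification

Stratified 80/20 train/validation splitting (train size = ⌊0.8 n⌋);
SMOTE balancing implemented per the standard interpolation rule — each
synthetic point is x + u(x_nn − x) with u ~ U(0,1) and x_nn one of the k=5
nearest within-class neighbors (k reduced and logged for very small
classes; single-member classes are an error). Majority points are never
altered and balanced inputs pass through unchanged. Algorithms are
random forest (200 trees), linear-kernel SVM (C = 1), logistic regression,
and gradient boosting (100 stages), wrapped one-vs-one or one-vs-rest;
hyperparameters are documented constants, with no tuning search.
Multi-class specificity is defined one-vs-rest per class. An 80/20 split
is the primary evaluation design; leave-one-out is available as an
optional mode.

Feature attribution offers Gini totals (tree ensembles), permutation
importance, and Monte-Carlo Shapley values: coalition values are means of
the model output over a background set with coalition features replaced by
the sample's values, estimated by averaging marginal contributions along
random feature permutations. Because each permutation telescopes, the
per-sample attributions sum exactly to prediction − baseline; accuracy of
individual values improves as O(1/√n_mc) and is checked against exhaustive
subset enumeration on small models.

## LuCIS

The composite score is fit on the bookend endotypes (least vs most
abnormal) of the *reference cohort* — the two largest pseudo-datasets,
which contain both bookends — because in-cohort severe samples anchor the
per-gene rank statistics and make unactivated modules binarize cleanly.
Scores are binarized at zero (exact zero → 0), and an L2-penalized
logistic regression (penalty chosen by 10-fold cross-validated deviance
over a log-spaced grid, λ = 1/C in scikit-learn's sum-form loss) provides
the coefficients. The patient score excludes the intercept: raw = Σ b_f
β_f, normalized by subtracting the minimum attainable raw value so scores
live on [0, max]; both attainable extremes are recorded in the model.
Sextile boundaries sit at i·max/6; sextile 1 is closed on the left and
later sextiles are half-open (lo, hi], so boundary scores belong to the
lower sextile; a 1e−12 absolute guard protects boundary values against
float rounding. Perfect separation at the weakest grid penalty is flagged.

## Score imputation

For a module unmeasured on a platform, the best-correlated measured module
in a reference cohort (Pearson, concatenated reference scores) supplies a
ratio coefficient c = mean[(s_target + 1)/(s_correlate + 1)]; imputation is
c(s + 1) − 1, clamped to [−1, 1] with a logged flag because downstream
binarization and cosine matching assume the enrichment range. Rules retain
ranked fallback correlates so a platform also lacking the primary
correlate imputes from the next-best measured one (logged). Rules
serialize with the coefficients so imputation is reproducible without the
reference data.

## Association statistics

Pearson chi-square without continuity correction by default (Yates
available as a flag); expected cells below 1 are flagged, not rejected.
Odds ratios are ad/bc with Woolf log-scale 95% intervals and the
Haldane–Anscombe 0.5 correction on zero cells (flagged). The trend test is
Cochran–Armitage with equally spaced scores 1..G by default (group indices
rather than dose scores), verified against R's `prop.trend.test`.
Kruskal–Wallis is tie-corrected; Dunn's post hoc z statistics use pooled
mean ranks with the standard tie term, Bonferroni-adjusted by default.
Type-I error of all three tests is checked to lie in [0.04, 0.06] at
α = 0.05 over 10,000 null simulations.

## Synthetic cohorts

The generator plants structure at the gene level so the whole pipeline —
filtering, scoring, discovery, classification, scoring, imputation — is
exercised end to end; a fast score-level generator exists for classifier
unit tests.

Defaults (the study-shaped configuration): 32 modules of 10 genes plus 200
background genes; eight endotypes with *nested* activation — endotype at
severity e perturbs the first 4e modules, endotype A none — in {−1, 0, +1}
(a fixed minority of modules, the lymphocyte-like ones, perturb downward,
and the down-regulated modules are distributed across severity steps so
each tier, including the top one, carries a robust differentiator);
planted effect δ = 1.5 log2 units = 3× the noise SD σ = 0.5; 17
pseudo-datasets at roughly 1/10 of the original per-dataset sizes (five
training sets of 80/80/28/14/16 patients plus twelve held-out sets,
~300 lupus samples and ~50 controls in total — sizes chosen so the full
suite runs in minutes at desk scale); six modules droppable per platform
to emulate microarray library restrictions, with 26 measured everywhere.
Every pseudo-dataset keeps endotype A, its most severe endotype and a few
controls, and per-dataset endotype composition is near-equal allocation:
both choices anchor the within-dataset rank statistics so the same
endotype scores comparably across heterogeneous cohort compositions, which
is what makes the planted profiles separable at the consensus cut of 1.8.
The two reference pseudo-datasets both contain the bookend endotypes, as
the original reference cohort did.

Clinical covariates are generated from the planted severity: an
activity score a₀ + a₁·(abnormal module count) + noise (a₀ = 2, a₁ = 0.4,
SD 2, floored at 0; controls 0), flare ~ Bernoulli(logistic(−2.5 + 0.4
severity)), response ~ Bernoulli(logistic(−1.5 + 0.15 severity + 0.8
treated)), ancestry mildly severity-tilted. These produce the qualitative
associations the analysis stages measure (lower flare odds in the least
abnormal endotype, rising flare frequency across sextiles) without
modeling any real trial's effect sizes.

What passing tests on these cohorts show — and do not show. The generator
produces Gaussian noise around planted means, independent genes within and
between modules, no batch, probe, or platform intensity effects, and
exactly exchangeable controls and least-abnormal patients. Recovery of the
planted structure therefore demonstrates the pipeline's correctness and
internal consistency, not its performance on real microarray/RNA-seq
compendia, where gene–gene correlation, batch structure and annotation
noise would loosen every margin observed here.

## Known limitations

Consensus letter ordering is a heuristic (mean signed enrichment) and can
transpose adjacent discovered endotypes relative to planted severity;
severity-ordered analyses should order groups by an external severity
measure when one exists. The Gaussian-kernel statistic is O(p·n²) in
memory per dataset; very large cohorts should use the ECDF kernel. Exact
tree-path Shapley values are out of scope; the Monte-Carlo estimator is
algorithm-agnostic but slower. The ridge fit relies on scikit-learn's
cross-validated logistic implementation; λ is reported on the sum-form
loss scale.
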