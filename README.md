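# lupus-endotypes

Molecular endotyping of systemic lupus erythematosus (SLE) blood
transcriptomes. SLE is clinically heterogeneous; patients with similar
presentations can carry very different immunologic abnormalities. This
package stratifies patients by *molecular endotype* instead: per-sample
enrichment of immune and inflammatory gene modules, unsupervised discovery
of patient subsets with cross-dataset consensus, supervised classification
of new samples into those subsets, and a composite score (LuCIS, the Lupus
Cell and Immune Score) summarizing the breadth of each patient's
immunologic perturbation. It is aimed at computational immunologists and
translational researchers working with whole-blood expression cohorts from
heterogeneous platforms.

## The methods at its core

**Module enrichment (GSVA-style scoring).** For a log2 expression matrix
X (genes × samples), each gene's expression is first re-expressed relative
to its cross-sample distribution, either by a Gaussian-kernel CDF estimate

  ẑᵢⱼ = (1/n) Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ),  hᵢ = sᵢ/4,

or by the empirical CDF. Within each sample, genes are ranked by
decreasing ẑ and given the symmetric rank weight w(r) = |p/2 − r + ½|. For
a gene set S of size m, a Kolmogorov–Smirnov-like random walk steps up by
w^τ/Σ_S w^τ at set members and down by 1/(p − m) elsewhere; the enrichment
score is the largest positive plus the largest negative deviation of the
walk and lies in [−1, 1].

**Endotype discovery.** Per dataset, k-means++ (best of many restarts by
inertia) on the module-score matrix, with k chosen from elbow and
silhouette diagnostics. Cluster mean-score profiles from all datasets are
compared by cosine similarity and merged by complete-linkage hierarchical
clustering cut at height 1.8, yielding the consensus endotype universe
(lettered A…H from least to most abnormal).

**Classification.** Random-forest / SVM / logistic / gradient-boosting
multi-class models (one-vs-one or one-vs-rest) trained on SMOTE-balanced
80/20 stratified splits, evaluated by sensitivity, specificity, F1,
Cohen's κ, and ROC/PR curves; centroid label transfer and Monte-Carlo
Shapley attribution are included for validation and interpretation.

**LuCIS.** Module scores are binarized (score > 0 → 1), and a
ridge-penalized logistic regression separating the least (A) from the most
(H) abnormal endotype provides per-module coefficients β. A patient's raw
score Σ b_f β_f is shifted by the minimum attainable value so scores live
on [0, max]; the range is divided into six equal sextiles for staging.
Scores missing on a platform are imputed from the best-correlated measured
module via a reference-cohort ratio rule: impute(s) = c(s + 1) − 1 with
c the mean reference ratio.

Because the underlying patient cohorts are controlled-access trial data,
the package ships a synthetic cohort generator that plants the same
statistical structure (eight nested-activation endotypes, 32 modules,
17 pseudo-datasets with platform feature dropout, severity-linked clinical
covariates) at the gene level, so every stage is exercised end to end.

## Worked example

```python
from lupus_endotypes.pipeline import run_pipeline
report = run_pipeline({"seed": 11})
```

On the default synthetic cohort this prints (via the report dict):

```
consensus endotypes: 8
per-dataset k: {'ds01': 6, 'ds02': 6, 'ds03': 5, 'ds04': 4, 'ds05': 5}
validation accuracy: 1.0 kappa: 1.0
mean LuCIS by endotype: {'A': 2.31, 'B': 3.85, 'C': 7.75, 'D': 16.58,
                         'E': 12.62, 'F': 19.8, 'G': 21.55, 'H': 22.52}
max LuCIS: 24.54
flare OR (A vs rest): 0.081
flare trend across sextiles p: 3.2e-15
activity Kruskal-Wallis p: 7.4e-56
```

Reading the numbers: five training pseudo-datasets individually contain
4–6 clusters whose consensus is exactly the eight planted endotypes; a
random forest assigns held-out samples to them essentially perfectly; the
composite score rises from the least (A) to the most (H) perturbed
endotype; patients in endotype A are far less likely to flare (odds ratio
≪ 1), flare frequency rises across LuCIS sextiles, and disease-activity
scores differ strongly across endotypes.

The same stages are available from the shell:

```
lupus-endotypes simulate --seed 3 --out sim/
lupus-endotypes gsva --matrix sim/ds01.tsv --gmt sim/modules.gmt --out scores.tsv
lupus-endotypes discover --scores scores.tsv --kmin 2 --kmax 8 --seed 1 --out disc/
```

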