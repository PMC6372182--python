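# covdeg

Multiclass differential-expression biomarker discovery built around the
pairwise-coverage statistic **COV**, with cross-series integration, mRMR
gene ranking and a cross-validated signature benchmark.

## The problem

Transcriptomic evidence for a disease family — here the motivating setting
is leukemia, with healthy bone marrow (HBM) and the four major leukemia
types (AML, ALL, CML, CLL) — is scattered across many public expression
series produced on different microarray and RNA-seq platforms. Finding a
compact gene signature that separates *all* the disease states at once
requires (i) integrating heterogeneous series into one comparable matrix
and (ii) a selection criterion that rewards genes discriminating many
class pairs, not just one disease against the rest.

## The method

Given N classes there are `COV_max = (N² − N) / 2` unordered one-vs-one
class comparisons (10 for N = 5). For each gene, a one-way group-means
model is fitted on the log2 scale and the per-gene residual variance s²_g
(on d_g = n − N df) is moderated by empirical Bayes: the hyperparameters
(d₀, s₀²) of the scaled inverse-chi-square prior are estimated by
moment-matching the log variances (digamma/trigamma relations), giving
the posterior variance

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g).

Every class pair (i, j) yields a moderated t-statistic
`t = (μ̂_i − μ̂_j) / √(s̃²_g (1/n_i + 1/n_j))` on d₀ + d_g df with a
two-sided p-value. A gene's **coverage** is

    COV_g = #{ pairs (i, j) : |LFC_ij| ≥ λ and p_ij ≤ α },

the number of class pairs the gene separates at log-fold-change threshold
λ and significance α. Genes with COV ≥ c (defaults λ = 2.5, α = 0.001,
c = 5) are the selected DEGs. They are ordered by greedy
minimum-redundancy maximum-relevance (plug-in mutual information on
3-state discretized expression, difference criterion), and top-n
signatures are benchmarked with SVM / kNN / naive Bayes / random forest
under stratified 5-fold cross-validation (accuracy and macro
f1 = mean over classes of 2·precision·recall/(precision+recall), computed
from pooled out-of-fold predictions, with per-fold scaling statistics
taken from the training fold only). A Type III main-effects ANOVA
attributes performance variance to the pipeline hyperparameters
(classifier, λ, c, signature size).

Upstream, samples are screened per series with the Kolmogorov–Smirnov
statistic Ka between each sample's expression distribution and the pooled
series distribution, series are merged on their common genes, and the
merged matrix is jointly quantile-normalized so every sample shares one
empirical distribution.

The package ships a synthetic-data generator that plants genes with known
class-mean profiles (hence known infinite-sample COV) among null genes,
across multiple series with affine batch effects — every stage is
testable against this ground truth without any downloads.

## Worked example

```python
import covdeg as cd

design = cd.default_design(seed=7)        # 5 classes (26/80/60/53/29 samples),
matrix, truth = cd.simulate_dataset(design)  # 2000 genes, 50 planted, 2 series
result = cd.run_discovery(matrix)         # qc -> merge -> normalize -> degs
print(result.degs.head(3))
```

```
gene_id  cov  mean_abs_t        mean_p  mean_abs_lfc
 G00047   10   57.897108  3.372264e-89      6.608596
 G00017   10   57.727634  1.864475e-87      6.594959
 G00023   10   56.623100  2.539104e-86      6.550533
```

Each row is a selected gene: `cov` is the number of the 10 class pairs it
separates at (λ = 2.5, α = 0.001); the remaining columns average |t|, p
and |LFC| over those covered pairs. On this run the 50 selected genes are
exactly the 50 planted ones (100% recall, 0 false selections). Ranking
the DEGs with mRMR and cross-validating the top-10 signature with kNN
gives accuracy 1.000 — the planted separation (Δ = 3 log2 units against
noise sd 0.5) makes the five classes fully recognizable, mirroring the
behaviour expected of a strong real signature. The scripts in
`examples/` walk through each capability, including a low-signal regime
where accuracy degrades gracefully and the ANOVA attributes the variance
to classifier and signature size.

The same pipeline is available as a CLI:

```bash
covdeg --seed 7 simulate --out m.tsv --truth t.tsv --ann ann.tsv
covdeg qc --in m.tsv --ann ann.tsv --out qc.tsv
covdeg normalize --in m.tsv --out norm.tsv
covdeg degs --in norm.tsv --ann ann.tsv --lfc 2.5 --pval 0.001 --cov 5 --out degs.tsv
covdeg rank --in norm.tsv --degs degs.tsv --ann ann.tsv --out ranking.tsv
covdeg evaluate --in norm.tsv --ann ann.tsv --ranking ranking.tsv --out results.tsv
covdeg anova --in results.tsv --response accuracy --out anova.tsv
```

## Layout

- `src/covdeg/` — library: `matrix` (data model + I/O), `simulate`,
  `qc`, `integrate`, `de` (coverage statistic + moderated contrasts),
  `mrmr`, `evaluate`, `anova`, `pipeline`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model assumptions, parameter choices, limitations
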