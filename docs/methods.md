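# Methods

## Data model and scope

The unit of analysis is a genes × samples matrix of log2-scale expression
values with two per-sample attributes: a class label (one of the disease
states under study) and a series identifier (the originating experiment
or platform batch). The package assumes gene-level, already-preprocessed
values: probe summarization, background correction and read-count
processing are upstream of its scope, and probe-to-gene collapsing across
platforms is taken as given. A `--log2` CLI flag applies log2(x+1) for
count-like inputs; otherwise no transform is applied on read. Empty
matrices are rejected at construction since every downstream stage needs
at least one gene and two classes.

## Outlier screening

Each sample's value distribution is compared with the pooled distribution
of its series by the two-sample Kolmogorov–Smirnov statistic Ka (ECDF
sup-distance, computed by `scipy.stats.ks_2samp`). The pool includes the
tested sample by default; `exclude_self` switches to leave-one-out
pooling. Because no absolute Ka threshold generalizes across platforms,
flagging uses a scale-free boxplot fence on the per-series Ka values,
Ka > Q3 + 1.5·IQR (multiplier configurable). On homogeneous data this
rule flags the upper tail of an unimodal Ka distribution, so occasional
benign flags are expected; a genuinely shifted array dominates the fence
by an order of magnitude. Screening runs per series, before merging, so
one aberrant platform cannot inflate the pooled reference.

## Integration

Series are merged on the intersection of their gene sets (gene order
follows the first matrix; sample ids must be disjoint), so normalization
never sees missing values. Joint quantile normalization maps every column
onto the row-wise mean of the column-sorted matrix. Ties are handled by
interpolating the reference at fractional average ranks, the convention
of limma's `normalizeQuantiles(ties=TRUE)` (a test verifies agreement
with that implementation). The transform is idempotent on tie-free data,
preserves within-column ranks, and makes the maximum ECDF distance
between any two columns exactly zero. Affine series effects (offset and
gain) are removed because they are rank-preserving.

Known limitation: in the sparse extremes of the distribution the
rank→reference mapping averages order statistics whose composition
differs between classes, so fold changes of genes sitting in the far tail
are compressed or stretched by a few tenths of a log2 unit. On the
default synthetic study this occasionally flips a borderline pair of a
planted gene (estimated COV off by one), while selection at COV ≥ 5 is
unaffected. On real data the same effect applies to extremely expressed
genes.

## Differential expression and coverage

Per gene, a one-way group-means model: class means by least squares and a
pooled within-class variance s²_g on d_g = n − N degrees of freedom
(every class must contribute ≥2 samples). Variances are moderated by
empirical Bayes under a scaled inverse-chi-square prior with
hyperparameters (d₀, s₀²) estimated by moment-matching the log residual
variances against their theoretical scaled-F distribution: with
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2)
determines d₀ through a Newton inversion of the trigamma function, and
the mean of e determines s₀². Zero (or negative) excess dispersion yields
d₀ = ∞ and complete shrinkage to the mean observed variance; exact-zero
variances are offset to 10⁻⁵ of the median before taking logs. These
conventions match the published moderated-t methodology, and a test
cross-checks hyperparameters and posterior variances against
Bioconductor limma's `squeezeVar` via Rscript. Forcing d₀ = 0 disables
moderation, in which case the two-class statistic reduces exactly to the
classical pooled-variance t-test (also under test).

All (N² − N)/2 unordered class pairs receive a moderated t and two-sided
p on d₀ + d_g df (normal when d₀ = ∞). A gene's coverage COV is the
number of pairs passing both |LFC| ≥ λ and p ≤ α. COV is monotone
non-increasing in λ and in decreasing α by construction. Defaults
λ = 2.5, α = 0.001 and selection at COV ≥ 5 (half of COV_max for five
classes) follow the study design this pipeline operationalizes.

Selected genes are reported with COV and mean |t|, mean p, mean |LFC|
averaged **over the covered pairs only** — averaging over all pairs would
dilute the statistics with the comparisons the gene does not discriminate.
This was a genuinely open choice; the covered-pairs reading keeps the
summary columns interpretable as "strength where the gene works". Output
is sorted by COV, then mean |t|, then gene id (deterministic). No
multiple-testing correction is applied to the per-pair p-values: the
selection gate is a raw α by design, and the triple restriction
(LFC, p, COV) is itself a stringent filter; a BH option exists on the
library surface for users who want it.

## mRMR ranking

Expression is discretized per gene into three states at mean ± k·sd
(default k = 1, the canonical preprocessing for mutual-information
feature selection on continuous expression; invariant to affine
transforms of a gene). Relevance is plug-in mutual information with the
class label in bits; redundancy is the mean MI with already-selected
genes. The greedy criterion is the difference scheme (MID),
relevance − redundancy, matching the additive "most relevance, least
redundancy" description; MIQ is available. Ties break lexicographically
by gene id so rankings are reproducible. The implementation is verified
against an independently coded brute-force greedy oracle on small
fixtures.

## Signature evaluation

Genes are scaled to median 0 / sd 1. Inside cross-validation the scaling
statistics come from the training fold only and are applied to the test
fold — the pure-noise leakage canary (expected accuracy 1/N) is part of
the test suite. Stratified folds deal each class's shuffled samples
round-robin across k folds from a rotating start, so per-fold class
counts stay within one of n_c/k even for the unbalanced class sizes of
the default study (26/80/60/53/29). The four classifiers are an
RBF-kernel SVM with one-vs-one voting over the (N−1)·N/2 binary machines,
kNN (k = 3), Gaussian naive Bayes and a 100-tree seeded random forest
(scikit-learn implementations; hyperparameters are harness defaults, all
configurable, not tuned claims). Headline accuracy and macro f1 (the
unweighted mean over classes of 2pr/(p+r), chosen over micro averaging so
small classes count equally) are computed from the pooled out-of-fold
confusion matrix, which is stabler for classes with ~26 samples than
averaging per-fold scores; per-fold values are retained.

## Hyperparameter ANOVA

Benchmark runs over the grid of classifier × LFC threshold × COV
threshold × signature size are analyzed with a main-effects linear model
under sum-to-zero coding. Type III sums of squares come from
full-vs-reduced least-squares comparisons (each factor's SS is the RSS
increase when its columns are dropped with all others retained), which in
balanced designs coincides with sequential SS — verified against a
closed-form balanced oracle and against statsmodels' Type III `anova_lm`
on balanced and unbalanced tables. A constant response reports SS = 0,
F = 0, p = 1 by convention; aliased factors raise an error naming them.

## Synthetic data generator

Each value is

    x[g, s] = scale(series(s)) · (b_g + μ[g, class(s)] + ε) + offset(series(s)),

ε ~ N(0, noise_sd²) i.i.d. on the log2 scale (matching the moderated-t
modelling assumption), with per-gene baselines b_g ~ N(baseline_mean,
baseline_sd²) constant across classes so null genes stay null. The
baseline spread (default 2.0, about the gene-to-gene spread of mean log2
expression in real compendia) gives the matrix a realistic dynamic range;
without it all null genes collapse onto one value and quantile
normalization becomes degenerate in the tails. Series effects are affine
(default: offsets 0 and +2, gains 1.0 and 1.2) because they emulate
platform differences in offset and dynamic range that joint quantile
normalization is able to remove.

The default study has 5 classes with sizes (26, 80, 60, 53, 29) echoing
the unbalance of a real leukemia compendium, 2000 genes, 50 planted,
noise sd 0.5 and separation unit Δ = 3. Planted class-mean patterns are
multiples of Δ chosen so the infinite-sample coverage at λ = 2.5 spans
exactly {5,…,10} (e.g. a 2-vs-3 split gives COV 6; the full ladder
0,Δ,2Δ,3Δ,4Δ gives COV 10). Patterns are mean-centred and rotated across
classes so that up- and down-shifts balance and no class monopolizes the
distribution tails. `planted_cov` (pair enumeration on the true means) is
the infinite-sample oracle for the pipeline's `compute_coverage`; their
agreement on the default fixture, and the chain-level recall of planted
genes at ≥95% with ≤1% null selections, are asserted in the acceptance
tests.

What the generator does **not** emulate: probe effects, missing values,
count noise (RNA-seq overdispersion), correlated gene modules, or
nonlinear batch distortions. Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under affine batch effects and
Gaussian noise — not robustness to every artifact of real compendia.

## Problem sizes

Tests and the acceptance script run the full chain on the 2000 × 248
default study (a desk-scale emulation of a multi-series compendium);
oracle-equivalence checks use small fixtures (≤200 genes) where
brute-force references are exact. All randomness is routed through
explicit integer seeds; identical seeds give bit-identical matrices and
fold assignments.
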