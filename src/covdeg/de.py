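"""Multiclass differential expression with the pairwise-coverage statistic.

The model is a per-gene one-way group-means fit: class means on the log2
scale plus a pooled within-class residual variance on ``n_total - n_classes``
degrees of freedom. Per-gene variances are moderated by empirical Bayes:
the sampling distribution of the residual variances is matched to a scaled
F / scaled chi-square prior with hyperparameters ``(d0, s0^2)`` estimated by
closed-form moments of the log variances (digamma/trigamma relations), and
each gene's variance is shrunk to the posterior

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g).

Every unordered class pair (i, j) then yields a moderated t-statistic

    t = (mu_i - mu_j) / sqrt(s~^2 * (1/n_i + 1/n_j))

on ``d0 + d_g`` degrees of freedom with a two-sided p-value.

A gene's COVERAGE (COV) is the number of class pairs for which it passes
both the |log-fold-change| >= lfc_threshold and p <= p_threshold gates; its
upper bound is cov_max(N) = (N^2 - N)/2, the number of unordered pairs.
Selected genes (COV >= cov_threshold) are reported with their COV and the
mean |t|, mean p and mean |LFC| over the pairs they cover.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix

__all__ = [
    "GroupFit",
    "EBayesParams",
    "PairwiseStats",
    "fit_class_means",
    "moderate_variances",
    "pairwise_stats",
    "cov_max",
    "compute_coverage",
    "select_degs",
    "extract_degs",
]


@dataclass
class GroupFit:
    """Per-gene class means and pooled within-class variance."""

    gene_ids: list[str]
    classes: list[str]
    means: np.ndarray  # genes x classes
    s2: np.ndarray  # pooled within-class variance, per gene
    df_resid: int  # n_total - n_classes, shared across genes
    n_per_class: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class EBayesParams:
    """Empirical-Bayes variance prior and per-gene posterior variances.

    ``d0`` may be ``inf`` (no excess dispersion among gene variances), in
    which case every posterior variance equals the prior ``s02``.
    """

    d0: float
    s02: float
    s2_post: np.ndarray

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be non-negative")
        if self.s02 <= 0:
            raise ValueError("prior variance must be positive")


@dataclass
class PairwiseStats:
    """All (N^2-N)/2 pairwise contrasts: LFC, moderated t and p per gene."""

    gene_ids: list[str]
    pairs: list[tuple[str, str]]
    lfc: np.ndarray  # genes x pairs, mu_i - mu_j
    t: np.ndarray
    p: np.ndarray
    df_total: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def fit_class_means(m: ExpressionMatrix) -> GroupFit:
    """One-way group-means fit per gene.

    Class means are sample means; the residual variance pools squared
    deviations over all classes on ``n_total - n_classes`` df.
    """
    if m.class_labels is None:
        raise ValueError("matrix has no class labels; attach annotations first")
    classes = m.classes
    labels = m.class_labels.to_numpy()
    n_per_class = np.array([(labels == c).sum() for c in classes])
    for c, n in zip(classes, n_per_class):
        if n < 2:
            raise ValueError(f"class {c!r} has {n} sample(s); need at least 2")
    n_total = int(n_per_class.sum())
    df = n_total - len(classes)
    if df < 1:
        raise ValueError("no residual degrees of freedom (n_total <= n_classes)")

    x = m.values.to_numpy()
    means = np.empty((m.n_genes, len(classes)))
    rss = np.zeros(m.n_genes)
    for k, c in enumerate(classes):
        block = x[:, labels == c]
        mu = block.mean(axis=1)
        means[:, k] = mu
        rss += ((block - mu[:, None]) ** 2).sum(axis=1)
    return GroupFit(
        gene_ids=m.gene_ids,
        classes=classes,
        means=means,
        s2=rss / df,
        df_resid=df,
        n_per_class=n_per_class,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def moderate_variances(fit: GroupFit, d0: float | None = None) -> EBayesParams:
    """Estimate the variance prior and shrink per-gene variances toward it.

    The hyperparameters are obtained by moment-matching the log residual
    variances against their theoretical scaled-F distribution: with
    ``e_g = log s_g^2 - digamma(d/2) + log(d/2)``,

        E[e]  = log s0^2 - digamma(d0/2) + log(d0/2)
        Var[e] = trigamma(d0/2) + trigamma(d/2)

    so ``d0`` comes from a trigamma inversion of the excess dispersion and
    ``s0^2`` from the mean. Zero excess dispersion yields ``d0 = inf`` and
    complete shrinkage to the common variance. Passing ``d0`` explicitly
    (e.g. 0 for no moderation) skips estimation of the prior df.
    """
    s2 = np.asarray(fit.s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        raise ValueError(
            "variance moderation needs at least 2 genes with positive "
            "residual variance (noise-free input?)"
        )
    d = float(fit.df_resid)

    if d0 == 0:
        return EBayesParams(d0=0.0, s02=float(np.median(s2[pos])), s2_post=s2.copy())

    # offset exact zeros slightly away from zero so log moments are defined
    med = float(np.median(s2))
    if med == 0:
        raise ValueError("more than half of the residual variances are zero")
    x = np.maximum(s2, 1e-5 * med)
    z = np.log(x)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, d / 2.0))

    if d0 is None:
        if evar > 0:
            d0_est = 2.0 * _trigamma_inverse(evar)
        else:
            d0_est = np.inf
    else:
        d0_est = float(d0)

    if np.isinf(d0_est):
        # zero excess dispersion: the prior is the mean observed variance
        s02 = float(x.mean())
        s2_post = np.full_like(s2, s02)
    else:
        s02 = float(
            np.exp(emean + special.digamma(d0_est / 2.0) - np.log(d0_est / 2.0))
        )
        s2_post = (d0_est * s02 + d * s2) / (d0_est + d)
    return EBayesParams(d0=d0_est, s02=s02, s2_post=s2_post)


def pairwise_stats(fit: GroupFit, eb: EBayesParams) -> PairwiseStats:
    """Moderated t and two-sided p for every unordered class pair."""
    C = len(fit.classes)
    pairs = list(combinations(range(C), 2))
    lfc = np.empty((fit.n_genes, len(pairs)))
    t = np.empty_like(lfc)
    df_total = eb.d0 + fit.df_resid
    for k, (i, j) in enumerate(pairs):
        lfc[:, k] = fit.means[:, i] - fit.means[:, j]
        se = np.sqrt(
            eb.s2_post * (1.0 / fit.n_per_class[i] + 1.0 / fit.n_per_class[j])
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t[:, k] = np.where(se > 0, lfc[:, k] / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.minimum(p, 1.0)
    return PairwiseStats(
        gene_ids=fit.gene_ids,
        pairs=[(fit.classes[i], fit.classes[j]) for i, j in pairs],
        lfc=lfc,
        t=t,
        p=p,
        df_total=float(df_total),
    )


def cov_max(n_classes: int) -> int:
    """Number of unordered class pairs, (N^2 - N)/2 — the COV upper bound."""
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    return (n_classes * n_classes - n_classes) // 2


def _covered(ps: PairwiseStats, lfc_threshold: float, p_threshold: float) -> np.ndarray:
    if lfc_threshold <= 0:
        raise ValueError(f"lfc_threshold must be positive, got {lfc_threshold}")
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must lie in (0,1), got {p_threshold}")
    return (np.abs(ps.lfc) >= lfc_threshold) & (ps.p <= p_threshold)


def compute_coverage(
    ps: PairwiseStats, lfc_threshold: float, p_threshold: float
) -> pd.Series:
    """COV per gene: pairs passing both the |LFC| and p-value gates."""
    cov = _covered(ps, lfc_threshold, p_threshold).sum(axis=1)
    return pd.Series(cov, index=ps.gene_ids, name="cov")


def select_degs(
    ps: PairwiseStats,
    lfc_threshold: float,
    p_threshold: float,
    cov_threshold: int,
) -> pd.DataFrame:
    """Genes with COV >= cov_threshold, with summaries over covered pairs.

    Columns: gene_id, cov, mean_abs_t, mean_p, mean_abs_lfc. The summaries
    average only the pairs the gene actually covers. Sorted by COV
    descending, then mean |t| descending, then gene id.
    """
    n_classes_pairs = ps.n_pairs
    if not 1 <= cov_threshold <= n_classes_pairs:
        raise ValueError(
            f"cov_threshold must lie in [1, {n_classes_pairs}], got {cov_threshold}"
        )
    mask = _covered(ps, lfc_threshold, p_threshold)
    cov = mask.sum(axis=1)
    rows = []
    for g in np.flatnonzero(cov >= cov_threshold):
        sel = mask[g]
        rows.append(
            {
                "gene_id": ps.gene_ids[g],
                "cov": int(cov[g]),
                "mean_abs_t": float(np.abs(ps.t[g, sel]).mean()),
                "mean_p": float(ps.p[g, sel].mean()),
                "mean_abs_lfc": float(np.abs(ps.lfc[g, sel]).mean()),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "cov", "mean_abs_t", "mean_p", "mean_abs_lfc"]
    )
    if len(out):
        out = out.sort_values(
            by=["cov", "mean_abs_t", "gene_id"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return out


def extract_degs(
    m: ExpressionMatrix,
    lfc_threshold: float = 2.5,
    p_threshold: float = 0.001,
    cov_threshold: int = 5,
    d0: float | None = None,
) -> pd.DataFrame:
    """Convenience chain: fit -> moderate -> contrasts -> COV selection."""
    fit = fit_class_means(m)
    eb = moderate_variances(fit, d0=d0)
    ps = pairwise_stats(fit, eb)
    return select_degs(ps, lfc_threshold, p_threshold, cov_threshold)
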