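"""Signature assessment: median/sd scaling, stratified k-fold CV, four
classifiers, accuracy and macro f1.

Genes are scaled to median 0 / sd 1; inside cross-validation the scaling
statistics come from the training fold only, so no information leaks from
test samples into the model. Folds are stratified: each fold's per-class
count is within one of n_c/k. Out-of-fold predictions from all k folds are
pooled into a single confusion matrix from which accuracy and the
unweighted (macro) f1 over classes — f1_c = 2*precision*recall /
(precision+recall) — are computed; per-fold metrics are also retained.

The four classifiers mirror a standard multiclass benchmark: an RBF-kernel
SVM with one-vs-one voting over the (N-1)*N/2 binary machines, k-nearest
neighbours (k=3), Gaussian naive Bayes, and a 100-tree random forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .matrix import ExpressionMatrix
from .mrmr import Ranking

__all__ = [
    "ConfusionMatrix",
    "CVResult",
    "scale_median_unit_sd",
    "stratified_folds",
    "macro_f1",
    "micro_f1",
    "evaluate_signature",
    "CLASSIFIERS",
]

CLASSIFIERS = ("SVM", "kNN", "NB", "RF")


def scale_median_unit_sd(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per gene: subtract the median, divide by the sample sd (ddof=1)."""
    x = m.values.to_numpy()
    sd = x.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-sd gene: {m.gene_ids[zero[0]]!r}")
    med = np.median(x, axis=1)
    return m.with_values((x - med[:, None]) / sd[:, None])


def stratified_folds(
    class_labels: pd.Series | np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Per-sample fold index in [0, k): class-stratified, seeded, deterministic.

    Within each class the (shuffled) samples are dealt round-robin across
    folds, starting from a rotating fold so remainders spread evenly;
    every fold's per-class count is within one of n_c/k.
    """
    y = np.asarray(pd.Series(class_labels).astype(str))
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=np.int64)
    start = 0
    for c in sorted(pd.unique(y)):
        idx = np.flatnonzero(y == c)
        if idx.size < k:
            raise ValueError(
                f"class {c!r} has {idx.size} samples, fewer than k={k} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = (np.arange(perm.size) + start) % k
        start = (start + perm.size) % k
    return folds


@dataclass
class ConfusionMatrix:
    """True × predicted counts over a fixed class list."""

    classes: list[str]
    counts: np.ndarray

    @classmethod
    def from_labels(
        cls, y_true: np.ndarray, y_pred: np.ndarray, classes: list[str] | None = None
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(str)
        y_pred = np.asarray(y_pred).astype(str)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        pos = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[pos[t], pos[p]] += 1
        return cls(classes=list(classes), counts=counts)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def _per_class_f1(cm: ConfusionMatrix) -> np.ndarray:
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    pred_tot = counts.sum(axis=0).astype(float)
    true_tot = counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return f1


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of 2*p*r/(p+r); 0 for empty p+r."""
    if cm.counts.size == 0 or cm.counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    if (cm.counts.sum(axis=1) == 0).any():
        raise ValueError("every class needs at least one true sample")
    return float(_per_class_f1(cm).mean())


def micro_f1(cm: ConfusionMatrix) -> float:
    """Micro-averaged f1 (equals accuracy for single-label multiclass)."""
    if cm.counts.size == 0 or cm.counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    return cm.accuracy


@dataclass
class CVResult:
    """Cross-validated performance of one classifier on one signature size."""

    classifier: str
    n_genes: int
    fold_accuracy: list[float]
    fold_f1: list[float]
    accuracy: float  # over pooled out-of-fold predictions
    f1: float
    seed: int
    confusion: ConfusionMatrix


def _make_classifier(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="rbf", decision_function_shape="ovo", random_state=seed)
    if name == "kNN":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "NB":
        return GaussianNB()
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _scale_train_test(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Median-0/sd-1 scaling with statistics from the training block only."""
    med = np.median(train, axis=1, keepdims=True)
    sd = train.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)  # constant-in-train gene: centre only
    return (train - med) / sd, (test - med) / sd


def evaluate_signature(
    m: ExpressionMatrix,
    ranking: Ranking | list[str],
    n_genes: int,
    classifier: str,
    k: int = 5,
    seed: int = 0,
    f1_average: str = "macro",
) -> CVResult:
    """Stratified k-fold CV of the top-``n_genes`` signature with one classifier.

    Scaling statistics are computed on each training fold only and applied
    to its test fold. Accuracy and f1 are computed from the pooled
    out-of-fold confusion matrix; per-fold values are retained in the
    result.
    """
    if m.class_labels is None:
        raise ValueError("matrix has no class labels; attach annotations first")
    genes = ranking.top(n_genes) if isinstance(ranking, Ranking) else list(ranking)[:n_genes]
    if len(genes) < n_genes:
        raise ValueError(f"ranking holds {len(genes)} genes; requested {n_genes}")
    sub = m.subset_genes(genes)
    x = sub.values.to_numpy()
    y = sub.class_labels.to_numpy()  # type: ignore[union-attr]
    classes = sorted(pd.unique(y))

    folds = stratified_folds(y, k, seed)
    y_pred = np.empty_like(y)
    fold_acc: list[float] = []
    fold_f1: list[float] = []
    f1_fn = macro_f1 if f1_average == "macro" else micro_f1
    for f in range(k):
        test = folds == f
        train = ~test
        xtr, xte = _scale_train_test(x[:, train], x[:, test])
        clf = _make_classifier(classifier, seed)
        clf.fit(xtr.T, y[train])
        pred = clf.predict(xte.T)
        y_pred[test] = pred
        cm_f = ConfusionMatrix.from_labels(y[test], pred, classes)
        fold_acc.append(cm_f.accuracy)
        fold_f1.append(f1_fn(cm_f))
    cm = ConfusionMatrix.from_labels(y, y_pred, classes)
    return CVResult(
        classifier=classifier,
        n_genes=n_genes,
        fold_accuracy=fold_acc,
        fold_f1=fold_f1,
        accuracy=cm.accuracy,
        f1=f1_fn(cm),
        seed=seed,
        confusion=cm,
    )
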