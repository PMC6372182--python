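"""Minimum-redundancy maximum-relevance gene ranking.

Expression is first discretized per gene into three states around the
gene's own mean (below mean - k*sd, within, above mean + k*sd) — the
canonical preprocessing for mutual-information feature selection on
continuous expression. Relevance is the plug-in mutual information
I(gene; class) in bits; redundancy is the mean MI with already-selected
genes. Ranking is greedy under the difference (MID) criterion:

    step t:  argmax_g  I(g; class) - (1/|S|) * sum_{s in S} I(g; s)

with ties broken by gene id for determinism. The quotient (MIQ) criterion
is available as an alternative scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "DiscreteMatrix",
    "Ranking",
    "discretize_expression",
    "mutual_information",
    "mrmr_rank",
]


@dataclass
class DiscreteMatrix:
    """Genes × samples integer states in {0,1,2} plus the cut parameters."""

    states: pd.DataFrame  # int states, genes x samples
    k_sigma: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.states.index)


def discretize_expression(m: ExpressionMatrix, k_sigma: float = 1.0) -> DiscreteMatrix:
    """Three-state discretization per gene at mean ± k_sigma * sd.

    State 0 below the lower cut, 2 above the upper cut, 1 in between.
    Invariant under any affine transform of a gene's values (positive
    scale). Errors on zero-variance genes, whose cuts would collapse.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    x = m.values.to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"zero-variance gene: {m.gene_ids[zero[0]]!r}")
    states = np.ones_like(x, dtype=np.int64)
    states[x < mu - k_sigma * sd] = 0
    states[x > mu + k_sigma * sd] = 2
    return DiscreteMatrix(
        states=pd.DataFrame(states, index=m.values.index, columns=m.values.columns),
        k_sigma=k_sigma,
    )


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("mutual_information: need two equal-length 1-D vectors")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())
    return max(mi, 0.0)  # clamp tiny negative rounding residue


@dataclass
class Ranking:
    """Ordered genes with the greedy score at each step and per-gene relevance."""

    genes: list[str]
    scores: list[float]
    relevance: pd.Series
    scheme: str

    def top(self, n: int) -> list[str]:
        if n > len(self.genes):
            raise ValueError(f"requested top {n} of a {len(self.genes)}-gene ranking")
        return self.genes[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.genes) + 1),
                "gene_id": self.genes,
                "score": self.scores,
                "relevance": self.relevance[self.genes].to_numpy(),
            }
        )


def mrmr_rank(
    d: DiscreteMatrix,
    class_labels: pd.Series | np.ndarray,
    m: int,
    scheme: str = "MID",
) -> Ranking:
    """Greedy mRMR ranking of the genes in ``d``.

    The first gene maximizes relevance I(g; class); each later step
    maximizes relevance minus (MID) or divided by (MIQ) the mean MI with
    the already-selected set. Deterministic: ties go to the
    lexicographically smallest gene id.
    """
    genes = d.gene_ids
    if not 1 <= m <= len(genes):
        raise ValueError(f"m must lie in [1, {len(genes)}], got {m}")
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    y = np.asarray(pd.Series(class_labels))
    X = d.states.to_numpy()
    if y.size != X.shape[1]:
        raise ValueError("class_labels length must equal number of samples")

    relevance = pd.Series(
        [mutual_information(X[i], y) for i in range(len(genes))], index=genes
    )
    remaining = set(range(len(genes)))

    # pairwise gene-gene MI computed lazily and cached
    cache: dict[tuple[int, int], float] = {}

    def gene_mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = mutual_information(X[i], X[j])
        return cache[key]

    selected: list[int] = []
    scores: list[float] = []
    for _ in range(m):
        best_idx = -1
        best_score = -np.inf
        for i in sorted(remaining, key=lambda i: genes[i]):
            rel = relevance.iloc[i]
            if selected:
                red = float(np.mean([gene_mi(i, j) for j in selected]))
                score = rel - red if scheme == "MID" else rel / (red + 1e-12)
            else:
                score = rel
            if score > best_score:
                best_score = score
                best_idx = i
        selected.append(best_idx)
        remaining.discard(best_idx)
        scores.append(float(best_score))
    return Ranking(
        genes=[genes[i] for i in selected],
        scores=scores,
        relevance=relevance,
        scheme=scheme,
    )
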