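"""Synthetic multi-series, multi-class expression data with planted effects.

The generator produces a genes × samples log2 expression matrix in which a
chosen subset of genes carries a planted class-mean profile while all other
genes are null (identical mean in every class). For each planted gene the
ground truth records the pairwise |Δ mean| matrix and the coverage the gene
attains at a given log-fold-change threshold in the infinite-sample limit
— the oracle against which the pipeline's COV estimates are checked.

Model per value:

    x[g, s] = scale(series(s)) * (baseline + mu[g, class(s)] + eps) + offset(series(s))

with eps ~ Normal(0, noise_sd^2) i.i.d. Noise is Gaussian on the log2 scale,
matching the modelling assumption of the moderated t-test downstream, and
series effects are affine so that joint quantile normalization can remove
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "simulate_dataset",
    "planted_cov",
    "default_design",
    "DEFAULT_PATTERNS",
]


def planted_cov(mean_vector: np.ndarray, lfc_threshold: float) -> int:
    """Number of unordered class pairs whose mean difference reaches the threshold.

    This is the infinite-sample coverage of a gene with the given class-mean
    profile: the value ``compute_coverage`` converges to as sample sizes grow
    and noise vanishes.
    """
    if lfc_threshold <= 0:
        raise ValueError(f"lfc_threshold must be positive, got {lfc_threshold}")
    mu = np.asarray(mean_vector, dtype=float)
    return sum(
        1 for i, j in combinations(range(len(mu)), 2) if abs(mu[i] - mu[j]) >= lfc_threshold
    )


@dataclass
class SimulationDesign:
    """Full description of a synthetic dataset.

    ``planted_genes`` maps gene index -> class-mean vector (log2 units,
    length ``n_classes``); all other genes are null. ``series_spec`` is a
    list of ``(series_id, additive_offset, multiplicative_scale)``; samples
    are assigned to series round-robin within each class so that class
    composition is balanced across series.
    """

    n_classes: int
    samples_per_class: list[int]
    n_genes: int
    planted_genes: dict[int, np.ndarray]
    noise_sd: float
    series_spec: list[tuple[str, float, float]]
    baseline_mean: float = 8.0
    baseline_sd: float = 0.0
    class_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if any(n < 1 for n in self.samples_per_class):
            raise ValueError("every class needs at least one sample")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.baseline_sd < 0:
            raise ValueError(f"baseline_sd must be non-negative, got {self.baseline_sd}")
        if not self.series_spec:
            raise ValueError("need at least one series")
        if self.class_names is None:
            self.class_names = [f"C{i + 1}" for i in range(self.n_classes)]
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        self.planted_genes = {
            int(g): np.asarray(mu, dtype=float) for g, mu in self.planted_genes.items()
        }
        for g, mu in self.planted_genes.items():
            if not 0 <= g < self.n_genes:
                raise ValueError(f"planted gene index {g} out of range")
            if mu.shape != (self.n_classes,):
                raise ValueError(
                    f"planted gene {g}: mean vector length {mu.shape[0]} != "
                    f"{self.n_classes} classes"
                )

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_class))


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``table`` has one row per planted gene: gene_id, the class means, and
    ``expected_cov`` — the infinite-sample coverage at ``lfc_threshold``.
    ``pairwise_lfc`` maps gene_id -> |Δ mean| per unordered class pair.
    """

    table: pd.DataFrame
    pairwise_lfc: dict[str, pd.Series]
    null_genes: list[str]
    lfc_threshold: float

    @property
    def planted_genes(self) -> list[str]:
        return list(self.table["gene_id"])

    def planted_with_cov_at_least(self, cov: int) -> list[str]:
        return list(self.table.loc[self.table["expected_cov"] >= cov, "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table[["gene_id", "expected_cov"]].copy()
        out["is_null"] = False
        nulls = pd.DataFrame(
            {"gene_id": self.null_genes, "expected_cov": 0, "is_null": True}
        )
        pd.concat([out, nulls], ignore_index=True).to_csv(
            Path(path), sep="\t", index=False
        )


def _assign_series(design: SimulationDesign) -> list[int]:
    """Round-robin series assignment within each class (per-sample series index)."""
    n_series = len(design.series_spec)
    out: list[int] = []
    for n_c in design.samples_per_class:
        out.extend(i % n_series for i in range(n_c))
    return out


def simulate_dataset(
    design: SimulationDesign, lfc_threshold: float = 2.5
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one dataset and its ground truth.

    The same design (including its seed) always yields a bit-identical
    matrix. ``lfc_threshold`` only parameterizes the ground-truth
    ``expected_cov`` column, not the data.
    """
    rng = np.random.default_rng(design.seed)
    G, S, C = design.n_genes, design.n_samples, design.n_classes

    class_of = np.repeat(np.arange(C), design.samples_per_class)
    series_of = np.asarray(_assign_series(design))

    mu = np.zeros((G, C))
    for g, vec in design.planted_genes.items():
        mu[g] = vec

    # per-gene baseline (constant across classes, so null genes stay null);
    # a spread > 0 gives the matrix a realistic dynamic range, which keeps
    # the rank -> reference-quantile mapping of joint quantile
    # normalization dense everywhere instead of degenerate in the tails
    baselines = design.baseline_mean + rng.normal(0.0, design.baseline_sd, size=G) \
        if design.baseline_sd > 0 else np.full(G, design.baseline_mean)

    signal = baselines[:, None] + mu[:, class_of]
    x = signal + rng.normal(0.0, design.noise_sd, size=(G, S))
    scales = np.array([s[2] for s in design.series_spec])
    offsets = np.array([s[1] for s in design.series_spec])
    x = x * scales[series_of] + offsets[series_of]

    gene_ids = [f"G{g:05d}" for g in range(G)]
    sample_ids = [f"S{s:04d}" for s in range(S)]
    assert design.class_names is not None
    labels = pd.Series([design.class_names[c] for c in class_of])
    series = pd.Series([design.series_spec[i][0] for i in series_of])

    m = ExpressionMatrix(
        values=pd.DataFrame(x, index=gene_ids, columns=sample_ids),
        class_labels=labels,
        series_ids=series,
    )

    pair_index = pd.Index(
        [f"{design.class_names[i]}|{design.class_names[j]}" for i, j in combinations(range(C), 2)]
    )
    rows = []
    pairwise: dict[str, pd.Series] = {}
    for g in sorted(design.planted_genes):
        vec = design.planted_genes[g]
        gid = gene_ids[g]
        diffs = np.array([abs(vec[i] - vec[j]) for i, j in combinations(range(C), 2)])
        pairwise[gid] = pd.Series(diffs, index=pair_index)
        rows.append(
            {
                "gene_id": gid,
                "expected_cov": planted_cov(vec, lfc_threshold),
                **{f"mu_{design.class_names[c]}": vec[c] for c in range(C)},
            }
        )
    planted_ids = {gene_ids[g] for g in design.planted_genes}
    truth = GroundTruth(
        table=pd.DataFrame(rows, columns=["gene_id", "expected_cov"]
                           + [f"mu_{c}" for c in design.class_names])
        if rows
        else pd.DataFrame(columns=["gene_id", "expected_cov"]),
        pairwise_lfc=pairwise,
        null_genes=[g for g in gene_ids if g not in planted_ids],
        lfc_threshold=lfc_threshold,
    )
    return m, truth


# Class-mean patterns (in units of the separation Δ before centring) whose
# pairwise coverage at threshold 2.5 with Δ=3 spans 5..10. Each pattern is
# mean-centred so up- and down-shifts balance around the baseline, and
# rotated across classes when planting so no class monopolizes the extreme
# tail of the sample distributions (quantile normalization would otherwise
# compress class-specific tails asymmetrically).
DEFAULT_PATTERNS: list[np.ndarray] = [
    np.array([0.0, 3.0, 4.0, 5.0, 6.0]),     # COV 5 at (Δ=3, thr 2.5)
    np.array([0.0, 0.0, 3.0, 3.0, 3.0]),     # COV 6
    np.array([0.0, 3.0, 6.0, 6.0, 6.0]),     # COV 7
    np.array([0.0, 0.0, 3.0, 3.0, 6.0]),     # COV 8
    np.array([0.0, 0.0, 3.0, 6.0, 9.0]),     # COV 9
    np.array([0.0, 3.0, 6.0, 9.0, 12.0]),    # COV 10
]


def default_design(
    seed: int = 0,
    n_genes: int = 2000,
    n_planted: int = 50,
    delta: float = 3.0,
    noise_sd: float = 0.5,
) -> SimulationDesign:
    """Desk-scale study emulation: 5 unbalanced classes, two affine series.

    Class sizes (26, 80, 60, 53, 29) echo the unbalance of a real
    leukemia compendium (healthy bone marrow plus four leukemia types);
    planted genes carry separations that are multiples of ``delta`` with
    infinite-sample coverage spanning 5..10 at the default LFC threshold
    of 2.5.
    """
    planted: dict[int, np.ndarray] = {}
    n_pat = len(DEFAULT_PATTERNS)
    for k in range(n_planted):
        pat = DEFAULT_PATTERNS[k % n_pat] * (delta / 3.0)
        shift = (k // n_pat) % 5
        rotated = np.roll(pat, shift)
        planted[k] = rotated - rotated.mean()
    return SimulationDesign(
        n_classes=5,
        samples_per_class=[26, 80, 60, 53, 29],
        n_genes=n_genes,
        planted_genes=planted,
        noise_sd=noise_sd,
        series_spec=[("seriesA", 0.0, 1.0), ("seriesB", 2.0, 1.2)],
        baseline_mean=8.0,
        baseline_sd=2.0,
        class_names=["HBM", "AML", "ALL", "CML", "CLL"],
        seed=seed,
    )
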