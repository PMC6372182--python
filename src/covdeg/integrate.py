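"""Cross-series integration: merge on shared genes, then joint quantile
normalization.

Series produced on different platforms share neither dynamic range nor
offset; after merging their matrices on the intersection of gene sets,
quantile normalization forces every sample (column) onto one common
empirical distribution — the row-wise mean of the column-sorted data —
while preserving each column's within-sample rank order. Ties within a
column receive the mean of the reference quantiles they span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["merge_by_gene", "quantile_normalize"]


def merge_by_gene(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices restricted to their common genes.

    Gene order follows the first matrix; samples keep input order; sample
    ids must be pairwise disjoint. Per-sample metadata is carried through
    when present on every input.
    """
    if len(matrices) < 2:
        raise ValueError("merge needs at least 2 matrices")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        counts = ", ".join(str(m.n_genes) for m in matrices)
        raise ValueError(
            f"no genes shared by all matrices (per-matrix gene counts: {counts})"
        )
    genes = [g for g in matrices[0].gene_ids if g in common]

    seen: set[str] = set()
    for m in matrices:
        overlap = seen & set(m.sample_ids)
        if overlap:
            raise ValueError(f"duplicate sample ids across matrices: {sorted(overlap)}")
        seen |= set(m.sample_ids)

    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    has_meta = all(m.class_labels is not None for m in matrices) and all(
        m.series_ids is not None for m in matrices
    )
    labels = series = None
    if has_meta:
        labels = pd.concat([m.class_labels for m in matrices])  # type: ignore[arg-type]
        series = pd.concat([m.series_ids for m in matrices])  # type: ignore[arg-type]
    return ExpressionMatrix(values=values, class_labels=labels, series_ids=series)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every column onto the mean-of-sorted-columns reference distribution.

    After the transform all columns share exactly the same sorted value
    vector, so the max ECDF distance between any two columns is zero;
    within each column ranks are preserved. Idempotent.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.values.to_numpy()
    if np.isnan(x).any():
        raise ValueError("quantile normalization: NaN values present")
    G, S = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    # fractional average ranks -> linear interpolation between reference
    # quantiles; ties thus receive the mean of the quantiles they span
    from scipy.stats import rankdata

    positions = np.arange(1.0, G + 1.0)
    for j in range(S):
        r = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(r, positions, reference)
    return m.with_values(out)
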