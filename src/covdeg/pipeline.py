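"""End-to-end discovery chain: per-series QC -> merge -> joint quantile
normalization -> coverage-based DEG selection."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import de, integrate, qc
from .matrix import ExpressionMatrix

__all__ = ["DiscoveryResult", "split_by_series", "run_discovery"]


def split_by_series(m: ExpressionMatrix) -> list[ExpressionMatrix]:
    """One matrix per series, in order of first appearance."""
    if m.series_ids is None:
        raise ValueError("matrix has no series ids attached")
    out = []
    for sid in pd.unique(m.series_ids):
        cols = [c for c in m.sample_ids if m.series_ids[c] == sid]
        out.append(m.subset_samples(cols))
    return out


@dataclass
class DiscoveryResult:
    qc_report: qc.OutlierReport
    normalized: ExpressionMatrix
    pairwise: de.PairwiseStats
    coverage: pd.Series
    degs: pd.DataFrame


def run_discovery(
    matrices: list[ExpressionMatrix] | ExpressionMatrix,
    lfc_threshold: float = 2.5,
    p_threshold: float = 0.001,
    cov_threshold: int = 5,
    iqr_multiplier: float = 1.5,
) -> DiscoveryResult:
    """Run the full chain on one annotated multi-series matrix or a list of
    per-series matrices.

    QC flags outliers within each series before merging; the merged matrix
    is jointly quantile-normalized; DEGs are selected by the
    (LFC, p, COV) triple restriction.
    """
    if isinstance(matrices, ExpressionMatrix):
        matrices = split_by_series(matrices)
    cleaned = []
    reports = []
    for m in matrices:
        report = qc.detect_outliers(m, iqr_multiplier=iqr_multiplier)
        reports.append(report.table)
        cleaned.append(qc.drop_flagged(m, report))
    qc_report = qc.OutlierReport(
        table=pd.concat(reports, ignore_index=True),
        iqr_multiplier=iqr_multiplier,
        exclude_self=False,
    )
    merged = integrate.merge_by_gene(cleaned) if len(cleaned) > 1 else cleaned[0]
    normalized = integrate.quantile_normalize(merged)
    fit = de.fit_class_means(normalized)
    eb = de.moderate_variances(fit)
    ps = de.pairwise_stats(fit, eb)
    coverage = de.compute_coverage(ps, lfc_threshold, p_threshold)
    degs = de.select_degs(ps, lfc_threshold, p_threshold, cov_threshold)
    return DiscoveryResult(
        qc_report=qc_report,
        normalized=normalized,
        pairwise=ps,
        coverage=coverage,
        degs=degs,
    )
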