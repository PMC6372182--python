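"""Outlier-sample screening via the Kolmogorov–Smirnov statistic.

Each sample's expression distribution is compared with the pooled
distribution of its series; the sup-distance Ka between the two empirical
CDFs flags arrays whose global distribution deviates from the rest (a
hybridization failure, a degradation artifact, a mislabeled platform).
Samples are screened per series, before merging and joint normalization.

The flagging rule is a scale-free boxplot fence on the per-series Ka
values: Ka > Q3 + 1.5*IQR, with the multiplier configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = ["OutlierReport", "ks_statistic", "detect_outliers"]


def ks_statistic(sample_values: np.ndarray, pooled_values: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic (ECDF sup-distance), in [0, 1]."""
    a = np.asarray(sample_values, dtype=float).ravel()
    b = np.asarray(pooled_values, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_statistic: empty input vector")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("ks_statistic: non-finite values")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


@dataclass
class OutlierReport:
    """Per-sample Ka and flag status plus the rule parameters used."""

    table: pd.DataFrame  # columns: sample_id, series, Ka, flagged
    iqr_multiplier: float
    exclude_self: bool

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "sample_id"])


def detect_outliers(
    m: ExpressionMatrix,
    iqr_multiplier: float = 1.5,
    exclude_self: bool = False,
) -> OutlierReport:
    """Compute Ka per sample against its series pool and flag outliers.

    ``exclude_self`` switches to leave-one-out pooling (the tested sample's
    values removed from the pool); by default the pool includes every
    sample of the series. Requires at least 3 samples per series for the
    fence to be meaningful.
    """
    if m.n_samples < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    series = (
        m.series_ids
        if m.series_ids is not None
        else pd.Series(["all"] * m.n_samples, index=m.values.columns)
    )
    rows = []
    for sid in pd.unique(series):
        cols = [c for c in m.sample_ids if series[c] == sid]
        if len(cols) < 3:
            raise ValueError(f"series {sid!r} has <3 samples; rule undefined")
        block = m.values[cols].to_numpy()
        pool_all = block.ravel()
        ka = np.empty(len(cols))
        for j, c in enumerate(cols):
            if exclude_self:
                pool = np.delete(block, j, axis=1).ravel()
            else:
                pool = pool_all
            ka[j] = ks_statistic(block[:, j], pool)
        q1, q3 = np.percentile(ka, [25, 75])
        fence = q3 + iqr_multiplier * (q3 - q1)
        for j, c in enumerate(cols):
            rows.append(
                {"sample_id": c, "series": sid, "Ka": ka[j], "flagged": bool(ka[j] > fence)}
            )
    table = pd.DataFrame(rows, columns=["sample_id", "series", "Ka", "flagged"])
    return OutlierReport(table=table, iqr_multiplier=iqr_multiplier, exclude_self=exclude_self)


def drop_flagged(m: ExpressionMatrix, report: OutlierReport) -> ExpressionMatrix:
    """Remove flagged samples from the matrix (no-op if nothing is flagged)."""
    keep = [s for s in m.sample_ids if s not in set(report.flagged)]
    if len(keep) == m.n_samples:
        return m
    return m.subset_samples(keep)
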