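"""Factorial ANOVA over pipeline hyperparameters (Type III sums of squares).

The benchmark runs form a table with categorical factors — classifier,
LFC threshold, COV threshold, signature size — and a response (accuracy or
f1). A main-effects linear model under sum-to-zero coding is fit by least
squares; each factor's Type III sum of squares is the increase in residual
sum of squares when that factor's columns are dropped from the full model,
which for unbalanced designs tests each main effect adjusted for all
others. F = MeanSq / MeanSq_residual with p from the F distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["factorial_anova"]


def _sum_to_zero_columns(levels: list, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero (effects) coding: L-1 columns; last level codes as -1."""
    L = len(levels)
    cols = np.zeros((values.size, L - 1))
    pos = {lv: i for i, lv in enumerate(levels)}
    for r, v in enumerate(values):
        i = pos[v]
        if i == L - 1:
            cols[r, :] = -1.0
        else:
            cols[r, i] = 1.0
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def factorial_anova(
    runs: pd.DataFrame, factors: list[str], response: str
) -> pd.DataFrame:
    """Main-effects Type III ANOVA table from a table of benchmark runs.

    Returns rows Source/SumSq/df/MeanSq/F/p for each factor plus
    ``Residuals`` and ``Corrected Total``. A constant response yields all
    SumSq 0 and the convention F=0, p=1. Errors if any factor has fewer
    than 2 levels, if no residual degrees of freedom remain, or if the
    design is rank-deficient (aliased factors).
    """
    if response not in runs.columns:
        raise ValueError(f"response column {response!r} not in table")
    missing = [f for f in factors if f not in runs.columns]
    if missing:
        raise ValueError(f"factor columns missing from table: {missing}")
    y = runs[response].to_numpy(dtype=float)
    n = y.size

    level_map: dict[str, list] = {}
    for f in factors:
        levels = sorted(pd.unique(runs[f]), key=str)
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        level_map[f] = levels

    blocks: dict[str, np.ndarray] = {
        f: _sum_to_zero_columns(level_map[f], runs[f].to_numpy()) for f in factors
    }
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [blocks[f] for f in factors])
    model_df = X_full.shape[1]
    if np.linalg.matrix_rank(X_full) < model_df:
        aliased = []
        kept = intercept
        for f in factors:
            cand = np.hstack([kept, blocks[f]])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                aliased.append(f)
            else:
                kept = cand
        raise ValueError(f"rank-deficient design; aliased factors: {aliased}")
    df_resid = n - model_df
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    rss_full = _rss(X_full, y)
    ms_resid = rss_full / df_resid
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    rows = []
    for f in factors:
        X_red = np.hstack(
            [intercept] + [blocks[g] for g in factors if g != f]
        )
        ss = max(_rss(X_red, y) - rss_full, 0.0)
        df_f = len(level_map[f]) - 1
        ms = ss / df_f
        if ms_resid > 0:
            F = ms / ms_resid
            p = float(stats.f.sf(F, df_f, df_resid))
        elif ss > 0:
            F, p = np.inf, 0.0
        else:
            F, p = 0.0, 1.0  # constant response convention
        rows.append(
            {"Source": f, "SumSq": ss, "df": df_f, "MeanSq": ms, "F": F, "p": p}
        )
    rows.append(
        {
            "Source": "Residuals",
            "SumSq": rss_full,
            "df": df_resid,
            "MeanSq": ms_resid,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "Source": "Corrected Total",
            "SumSq": ss_total,
            "df": n - 1,
            "MeanSq": np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["Source", "SumSq", "df", "MeanSq", "F", "p"])
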