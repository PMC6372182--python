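"""Expression-matrix data model and delimited-text I/O.

The central container is :class:`ExpressionMatrix`: a genes × samples table
of log2-scale expression values together with optional per-sample class
labels (the disease states of a multiclass study) and series identifiers
(the originating experiment/batch, e.g. one microarray or RNA-seq series).

On disk a matrix is a TSV (or CSV, auto-detected by extension) whose first
column is ``gene_id`` and whose header row carries the sample ids — the
common orientation of gene-level series matrices. Values are assumed to be
already on the log2 scale; no transform is applied on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "attach_annotations",
]

GENE_COLUMN = "gene_id"


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns; all
        entries must be finite floats on the log2 scale.
    class_labels
        Optional per-sample class label (e.g. HBM/AML/ALL/CML/CLL),
        aligned with ``values.columns``.
    series_ids
        Optional per-sample series/batch identifier, aligned with
        ``values.columns``.
    """

    values: pd.DataFrame
    class_labels: pd.Series | None = None
    series_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError(
                "empty expression matrix: need at least 1 gene and 1 sample"
            )
        dup = _first_duplicate(list(self.values.index))
        if dup is not None:
            raise ValueError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(list(self.values.columns))
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.values = self.values.astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        for name in ("class_labels", "series_ids"):
            s = getattr(self, name)
            if s is not None:
                s = pd.Series(s)
                if len(s) != self.n_samples:
                    raise ValueError(
                        f"{name} has length {len(s)}, expected {self.n_samples}"
                    )
                s.index = self.values.columns
                setattr(self, name, s.astype(str))

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        if self.class_labels is None:
            raise ValueError("matrix has no class labels attached")
        return sorted(self.class_labels.unique())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples (in the given order)."""
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(
            values=self.values[list(sample_ids)].copy(),
            class_labels=None
            if self.class_labels is None
            else self.class_labels[list(sample_ids)],
            series_ids=None
            if self.series_ids is None
            else self.series_ids[list(sample_ids)],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            class_labels=self.class_labels,
            series_ids=self.series_ids,
        )

    def with_values(self, values: np.ndarray | pd.DataFrame) -> "ExpressionMatrix":
        """Same genes/samples/metadata with a replaced value matrix."""
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.values.index,
            columns=self.values.columns,
        )
        return ExpressionMatrix(
            values=df, class_labels=self.class_labels, series_ids=self.series_ids
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """One sample's metadata: id, class label and series of origin."""

    sample_id: str
    class_label: str
    series_id: str

    def __post_init__(self) -> None:
        if not self.class_label:
            raise ValueError(f"empty class label for sample {self.sample_id!r}")


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path, dialect: str | None = None
) -> ExpressionMatrix:
    """Read a genes × samples matrix from delimited text.

    First column: gene ids (header ``gene_id``); remaining columns:
    samples. ``dialect`` is the field delimiter; by default ``,`` for
    ``.csv`` files and tab otherwise.
    """
    path = Path(path)
    sep = _dialect_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: expected a gene-id column plus ≥1 sample column "
            f"(got {df.shape[1]} columns; wrong delimiter?)"
        )
    gene_ids = df.iloc[:, 0].astype(str)
    dup = _first_duplicate(list(gene_ids))
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene id: {dup!r}")
    body = df.iloc[:, 1:]
    try:
        values = body.astype(float)
    except ValueError:
        for j, col in enumerate(body.columns):
            for i, cell in enumerate(body[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row "
                        f"{i + 2}, column {j + 2} (gene {gene_ids.iloc[i]!r}, "
                        f"sample {col!r})"
                    ) from None
        raise
    values.index = pd.Index(gene_ids, name=GENE_COLUMN)
    return ExpressionMatrix(values=values)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as delimited text; full float precision (round-trips)."""
    path = Path(path)
    sep = _dialect_for(path, None)
    out = m.values.copy()
    out.index.name = GENE_COLUMN
    # repr-precision serialization so read(write(m)) is bit-identical
    out.to_csv(path, sep=sep, float_format=None)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample-annotation table (columns sample_id, class, series)."""
    path = Path(path)
    sep = _dialect_for(path, None)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("sample_id", "class", "series") if c not in cols]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    return [
        SampleAnnotation(
            sample_id=row[cols["sample_id"]],
            class_label=row[cols["class"]],
            series_id=row[cols["series"]],
        )
        for _, row in df.iterrows()
    ]


def write_annotations(
    m: ExpressionMatrix, path: str | Path
) -> None:
    """Write the matrix's sample metadata as a TSV annotation table."""
    if m.class_labels is None or m.series_ids is None:
        raise ValueError("matrix has no annotations to write")
    pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "class": m.class_labels.to_numpy(),
            "series": m.series_ids.to_numpy(),
        }
    ).to_csv(Path(path), sep="\t", index=False)


def attach_annotations(
    m: ExpressionMatrix, ann: Iterable[SampleAnnotation]
) -> ExpressionMatrix:
    """Attach class labels and series ids to a matrix, in matrix sample order.

    Every sample of ``m`` must be annotated; annotations for unknown
    samples are ignored with a warning. The result is independent of the
    order of the annotation table.
    """
    ann = list(ann)
    by_id: dict[str, SampleAnnotation] = {}
    for a in ann:
        if a.sample_id in by_id:
            raise ValueError(f"duplicate annotation for sample {a.sample_id!r}")
        by_id[a.sample_id] = a
    missing = [s for s in m.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    extra = set(by_id) - set(m.sample_ids)
    if extra:
        warnings.warn(
            f"ignoring annotations for unknown samples: {sorted(extra)}",
            stacklevel=2,
        )
    return ExpressionMatrix(
        values=m.values.copy(),
        class_labels=pd.Series([by_id[s].class_label for s in m.sample_ids]),
        series_ids=pd.Series([by_id[s].series_id for s in m.sample_ids]),
    )
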