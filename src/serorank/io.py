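"""Reading and writing feature tables, label lists and ranking output.

A feature table is delimited text (TSV by default, CSV by flag), one row per
protein: an identifier column followed by a fixed-width numeric feature
vector.  A label file lists identifiers of known positives, optionally with a
second column distinguishing ``positive`` from ``negative``.  Ranking output
is ``id<TAB>rank<TAB>score`` with scores printed to 6 significant digits.

Missing or non-numeric cells are hard errors: the ranking model assumes
complete feature vectors, and silent imputation would corrupt the distance
geometry everything downstream depends on.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "LabelAssignment",
    "FormatError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_ranking",
]


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, ...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a table/label invariant."""


@dataclass(frozen=True)
class FeatureTable:
    """An ordered set of samples with an ``n x m`` real feature matrix.

    Attributes
    ----------
    ids:
        Unique sample identifiers, in input row order.
    X:
        Feature matrix of shape ``(n, m)``; all values finite.
    """

    ids: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if X.ndim != 2:
            raise ValidationError(f"feature matrix must be 2-D, got shape {X.shape}")
        if len(self.ids) != X.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} ids but {X.shape[0]} feature rows"
            )
        if X.shape[0] < 2:
            raise ValidationError("need at least 2 samples")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate ids: {dupes}")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValidationError(
                f"non-finite feature value at row {bad[0]} column {bad[1]}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset preserving order of *indices*."""
        idx = list(indices)
        return FeatureTable(tuple(self.ids[i] for i in idx), self.X[idx])


@dataclass(frozen=True)
class LabelAssignment:
    """Query status per sample: positive (query), negative, or unlabeled.

    Derived score vectors:

    * ``y``       — 1 on positives, 0 elsewhere (positive-only ranking seed)
    * ``y_plus``  — identical to ``y``
    * ``y_minus`` — −1 on known negatives, 0 elsewhere (universal variant)
    """

    n: int
    positive: np.ndarray  # bool mask
    negative: np.ndarray  # bool mask

    def __post_init__(self) -> None:
        pos = np.asarray(self.positive, dtype=bool)
        neg = np.asarray(self.negative, dtype=bool)
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)
        if pos.shape != (self.n,) or neg.shape != (self.n,):
            raise ValidationError("label masks must have length n")
        if not pos.any():
            raise ValidationError("at least one positive (query) is required")
        if (pos & neg).any():
            raise ValidationError("positive and negative sets must be disjoint")

    @classmethod
    def from_sets(
        cls,
        table: FeatureTable,
        positives: Iterable[str],
        negatives: Iterable[str] = (),
    ) -> "LabelAssignment":
        pos_ids, neg_ids = set(positives), set(negatives)
        known = set(table.ids)
        unknown = sorted((pos_ids | neg_ids) - known)
        if unknown:
            raise ValidationError(f"ids not present in the feature table: {unknown}")
        pos = np.array([i in pos_ids for i in table.ids])
        neg = np.array([i in neg_ids for i in table.ids])
        if pos.all():
            # queries must leave something to rank; an all-positive subset can
            # still arise later (e.g. after aggressive prefiltering)
            raise ValidationError("positives must be a proper subset of samples")
        return cls(table.n, pos, neg)

    @property
    def y(self) -> np.ndarray:
        return self.positive.astype(float)

    @property
    def y_plus(self) -> np.ndarray:
        return self.y

    @property
    def y_minus(self) -> np.ndarray:
        return -self.negative.astype(float)

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    @property
    def n_negative(self) -> int:
        return int(self.negative.sum())

    @property
    def unlabeled(self) -> np.ndarray:
        return ~(self.positive | self.negative)

    def subset(self, indices: Sequence[int]) -> "LabelAssignment":
        idx = list(indices)
        return LabelAssignment(len(idx), self.positive[idx], self.negative[idx])


def _float(cell: str, line_no: int, col: int) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise FormatError(
            f"non-numeric cell {cell!r} at line {line_no}, column {col}"
        ) from None
    if not np.isfinite(value):
        raise FormatError(f"non-finite cell {cell!r} at line {line_no}, column {col}")
    return value


def read_feature_table(
    path: str | Path,
    id_column: int | str = 0,
    delimiter: str = "\t",
    header: bool = False,
) -> FeatureTable:
    """Parse a delimited feature table into a validated :class:`FeatureTable`.

    Parameters
    ----------
    path:
        Delimited text file, UTF-8.
    id_column:
        Column holding the identifier; an integer position, or a column name
        when ``header`` is true.
    delimiter:
        ``"\\t"`` (default) or ``","``.
    header:
        Whether the first row is a header.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [(no, row) for no, row in enumerate(csv.reader(fh, delimiter=delimiter), 1)
                if row and any(c.strip() for c in row)]
    if not rows:
        raise FormatError(f"{path}: empty file")

    col_names: list[str] | None = None
    if header:
        col_names = [c.strip() for c in rows[0][1]]
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: header but no data rows")
    if isinstance(id_column, str):
        if col_names is None:
            raise ValidationError("id_column by name requires header=True")
        try:
            id_idx = col_names.index(id_column)
        except ValueError:
            raise ValidationError(
                f"id column {id_column!r} not in header {col_names}"
            ) from None
    else:
        id_idx = int(id_column)

    width = len(rows[0][1])
    ids: list[str] = []
    data: list[list[float]] = []
    for line_no, row in rows:
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row at line {line_no}: "
                f"expected {width} fields, found {len(row)}"
            )
        ids.append(row[id_idx].strip())
        data.append(
            [_float(c, line_no, j) for j, c in enumerate(row) if j != id_idx]
        )
    table = FeatureTable(tuple(ids), np.array(data))
    logger.info("read %d samples x %d features from %s", table.n, table.m, path)
    return table


def write_feature_table(
    table: FeatureTable, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a table back to delimited text (full ``repr`` precision)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, sid in enumerate(table.ids):
            fh.write(delimiter.join([sid] + [repr(float(v)) for v in table.X[i]]) + "\n")


def read_labels(path: str | Path, table: FeatureTable) -> LabelAssignment:
    """Read a query/label file against *table*.

    One identifier per line marks a positive; an optional second
    tab-separated column may say ``positive`` or ``negative``.  Identifiers
    absent from the table are an error; table ids not listed stay unlabeled.
    """
    positives: list[str] = []
    negatives: list[str] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.strip().split("\t")
            if not parts or not parts[0] or parts[0].startswith("#"):
                continue
            status = parts[1].strip().lower() if len(parts) > 1 else "positive"
            if status == "positive":
                positives.append(parts[0])
            elif status == "negative":
                negatives.append(parts[0])
            else:
                raise FormatError(
                    f"{path}: line {line_no}: unknown label {status!r} "
                    "(expected 'positive' or 'negative')"
                )
    labels = LabelAssignment.from_sets(table, positives, negatives)
    logger.info(
        "labels: %d positive, %d negative, %d unlabeled",
        labels.n_positive, labels.n_negative, int(labels.unlabeled.sum()),
    )
    return labels


def write_ranking(
    ids: Sequence[str],
    scores: np.ndarray,
    path: str | Path,
    top_n: int | None = None,
) -> None:
    """Write the ``top_n`` highest-scoring samples as ``id<TAB>rank<TAB>score``.

    Sort is by descending score with ties broken by input row order, so
    output is deterministic.  ``top_n`` larger than ``n`` is clamped with a
    warning; ``top_n=0`` writes the header only.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(ids)
    if top_n is None:
        top_n = n
    if top_n > n:
        logger.warning("top_n=%d exceeds n=%d; clamping", top_n, n)
        top_n = n
    order = np.argsort(-scores, kind="stable")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\trank\tscore\n")
        for rank, idx in enumerate(order[:top_n], 1):
            fh.write(f"{ids[idx]}\t{rank}\t{scores[idx]:.6g}\n")
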