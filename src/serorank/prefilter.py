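"""Nearest-positive-distance prefilter.

Manifold ranking costs O(n^3); for proteome-scale inputs the candidate pool
is first reduced by dropping the ``k`` unlabeled samples farthest (by
Euclidean distance to their nearest labeled positive) from the query set.
Known positives are never dropped, and known negatives are protected by
default since only "unknown" samples are candidates for removal.

The same nearest-positive distance doubles as a simple ranking baseline
(see :mod:`serorank.evaluation`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import FeatureTable, LabelAssignment

__all__ = ["FilterReport", "nearest_positive_distance", "filter_bottom_k"]


@dataclass(frozen=True)
class FilterReport:
    retained_ids: tuple[str, ...]
    dropped_ids: tuple[str, ...]
    distances: np.ndarray  # nearest-positive distance, retained then dropped order
    k: int

    def write(self, path) -> None:
        dropped = set(self.dropped_ids)
        ids = list(self.retained_ids) + list(self.dropped_ids)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tnearest_positive_distance\tdropped\n")
            for sid, d in zip(ids, self.distances):
                fh.write(f"{sid}\t{d:.6g}\t{int(sid in dropped)}\n")


def nearest_positive_distance(
    table: FeatureTable, labels: LabelAssignment
) -> np.ndarray:
    """Per-sample Euclidean distance to the closest labeled positive.

    Positives themselves score 0 (each is its own nearest positive).
    """
    pos_X = table.X[labels.positive]
    d = cdist(table.X, pos_X, metric="euclidean").min(axis=1)
    d[labels.positive] = 0.0
    return d


def filter_bottom_k(
    table: FeatureTable,
    labels: LabelAssignment,
    k: int,
    protect_negatives: bool = True,
) -> tuple[FeatureTable, LabelAssignment, FilterReport]:
    """Drop the ``k`` eligible samples with the largest nearest-positive distance.

    Eligible means unlabeled (plus known negatives when
    ``protect_negatives=False``).  Ties in distance are broken by input row
    order, and the retained subset preserves original row order.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    d = nearest_positive_distance(table, labels)
    eligible = labels.unlabeled if protect_negatives else ~labels.positive
    max_k = int(eligible.sum())
    if k > max_k:
        raise ValueError(f"k={k} exceeds the {max_k} filterable samples")

    elig_idx = np.flatnonzero(eligible)
    # stable sort descending by distance: farthest first, ties by row order
    order = elig_idx[np.argsort(-d[elig_idx], kind="stable")]
    dropped = set(order[:k].tolist())
    retained_idx = [i for i in range(table.n) if i not in dropped]

    report = FilterReport(
        retained_ids=tuple(table.ids[i] for i in retained_idx),
        dropped_ids=tuple(table.ids[i] for i in sorted(dropped)),
        distances=d[retained_idx + sorted(dropped)],
        k=k,
    )
    return table.subset(retained_idx), labels.subset(retained_idx), report
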