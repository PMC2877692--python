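"""Recall-precision evaluation, the query-subsampling benchmark, and baselines.

Ranked retrieval of held-out positives is scored by the area under the
recall-precision curve, computed as average precision: sweep the descending
score order, and at each true-positive rank accumulate precision-at-that-rank
divided by the total number of positives (step integration, no
interpolation).  Query samples are always excluded before the curve is
built — the task is retrieving the positives the ranker was *not* told
about.

The benchmark protocol repeatedly subsamples small query sets from the known
positives (e.g. 10/20/30 queries, five repeats), runs every registered
method on identical queries, and averages PR-AUC over repeats.  Baselines:
the nearest-positive-distance ranker, a binary SVM trained on the queries
against sampled negatives, and a one-class SVM trained on the queries alone,
each ranking by signed distance to the decision boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC, OneClassSVM

from .graph import build_affinity, estimate_sigma, normalize, pairwise_distances
from .io import FeatureTable, LabelAssignment
from .prefilter import nearest_positive_distance
from .ranking import RankingParams, rank_closed_form

logger = logging.getLogger(__name__)

__all__ = [
    "PRCurve",
    "BenchmarkReport",
    "pr_curve",
    "nearest_distance_ranker",
    "manifold_ranker",
    "manifold_sparse_ranker",
    "svm_ranker",
    "run_benchmark",
    "METHODS",
]


@dataclass(frozen=True)
class PRCurve:
    """Recall/precision pairs over descending-score prefixes, plus the AUC."""

    recall: np.ndarray
    precision: np.ndarray
    auc: float


def pr_curve(
    scores: np.ndarray,
    truth: np.ndarray,
    exclude: np.ndarray | list | None = None,
) -> PRCurve:
    """Recall-precision curve and its area (average precision).

    Parameters
    ----------
    scores:
        Ranking scores, higher = more positive-like.
    truth:
        Binary ground-truth labels aligned with ``scores``.
    exclude:
        Indices to remove before the curve is built (the query samples).

    Ties in score keep input order (stable sort), so the curve is
    deterministic; fully tied scores are legal but logged as a warning.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    keep = np.ones(scores.size, dtype=bool)
    if exclude is not None and len(np.atleast_1d(exclude)) > 0:
        keep[np.asarray(exclude, dtype=int)] = False
    s, t = scores[keep], truth[keep]
    P = int(t.sum())
    if P == 0:
        raise ValueError("no true positives among the evaluated samples")
    if s.size > 1 and np.ptp(s) == 0.0:
        logger.warning("all scores tied; curve follows input order")

    order = np.argsort(-s, kind="stable")
    hits = t[order]
    tp = np.cumsum(hits)
    ranks = np.arange(1, s.size + 1)
    precision = tp / ranks
    recall = tp / P
    auc = float(precision[hits].sum() / P)
    return PRCurve(recall=recall, precision=precision, auc=auc)


# ---------------------------------------------------------------------------
# rankers: uniform signature (table, labels, *, rng, ctx) -> scores
# ctx carries per-dataset precomputations shared across benchmark repeats.


def _ctx_graph(table: FeatureTable, ctx: dict | None):
    if ctx is not None and "L" in ctx:
        return ctx["L"]
    D = pairwise_distances(table)
    L = normalize(build_affinity(D, estimate_sigma(D)))
    if ctx is not None:
        ctx["L"] = L
    return L


def _ctx_sigma(table: FeatureTable, ctx: dict | None) -> float:
    if ctx is not None and "sigma" in ctx:
        return ctx["sigma"]
    sigma = estimate_sigma(pairwise_distances(table))
    if ctx is not None:
        ctx["sigma"] = sigma
    return sigma


def manifold_ranker(
    table: FeatureTable,
    labels: LabelAssignment,
    params: RankingParams | None = None,
    rng: np.random.Generator | None = None,
    ctx: dict | None = None,
) -> np.ndarray:
    """Positive-only manifold ranking scores on the dense affinity graph."""
    L = _ctx_graph(table, ctx)
    return rank_closed_form(L, labels.y, params or RankingParams()).scores


def manifold_sparse_ranker(
    table: FeatureTable,
    labels: LabelAssignment,
    params: RankingParams | None = None,
    b: int | None = None,
    rng: np.random.Generator | None = None,
    ctx: dict | None = None,
) -> np.ndarray:
    """Manifold ranking on the b-matching-sparsified graph (full pipeline)."""
    from .sparsify import apply_sparsification, default_budget, solve_bmatching

    key = ("L_sparse", b)
    if ctx is None or key not in (ctx or {}):
        D = pairwise_distances(table)
        graph = build_affinity(D, estimate_sigma(D))
        budget = b if b is not None else default_budget(table.n)
        sparse = apply_sparsification(graph, solve_bmatching(graph, budget))
        L = normalize(sparse)
        if ctx is not None:
            ctx[key] = L
    else:
        L = ctx[key]
    return rank_closed_form(L, labels.y, params or RankingParams()).scores


def nearest_distance_ranker(
    table: FeatureTable,
    labels: LabelAssignment,
    rng: np.random.Generator | None = None,
    ctx: dict | None = None,
) -> np.ndarray:
    """Baseline: negated distance to the nearest labeled positive."""
    return -nearest_positive_distance(table, labels)


def svm_ranker(
    table: FeatureTable,
    labels: LabelAssignment,
    strategy: str = "binary",
    negative_multiple: int = 100,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    ctx: dict | None = None,
    allow_unlabeled_negatives: bool = True,
) -> np.ndarray:
    """Rank by signed distance to an SVM decision boundary.

    ``strategy="binary"`` trains a maximum-margin classifier on the queries
    against ``negative_multiple * q`` sampled negatives — known negatives
    when present, otherwise (flagged by ``allow_unlabeled_negatives``)
    unlabeled samples treated as negatives, the usual PU expedient.
    ``strategy="one_class"`` fits a one-class support-region model on the
    queries alone.  The RBF bandwidth is tied to the graph kernel's sigma so
    both model families see the same feature geometry.
    """
    if strategy not in ("binary", "one_class"):
        raise ValueError(f"unknown SVM strategy {strategy!r}")
    q = labels.n_positive
    sigma = _ctx_sigma(table, ctx)
    gamma = 1.0 / (2.0 * sigma ** 2)
    if rng is None:
        rng = np.random.default_rng(seed)

    if strategy == "one_class":
        if q < 2:
            raise ValueError("one-class SVM needs at least 2 positive queries")
        model = OneClassSVM(kernel="rbf", gamma=gamma, nu=0.1)
        model.fit(table.X[labels.positive])
        return model.decision_function(table.X)

    if labels.n_negative > 0:
        neg_pool = np.flatnonzero(labels.negative)
    elif allow_unlabeled_negatives:
        logger.info("no known negatives; sampling unlabeled samples as negatives")
        neg_pool = np.flatnonzero(labels.unlabeled)
    else:
        raise ValueError("binary SVM requires known negatives")
    if neg_pool.size == 0:
        raise ValueError("no negative samples available for binary SVM")
    n_neg = min(negative_multiple * q, neg_pool.size)
    neg_idx = rng.choice(neg_pool, size=n_neg, replace=False)

    train = np.concatenate([np.flatnonzero(labels.positive), neg_idx])
    y_train = np.concatenate([np.ones(q), np.zeros(n_neg)])
    model = SVC(kernel="rbf", gamma=gamma, C=1.0)
    model.fit(table.X[train], y_train)
    return model.decision_function(table.X)


METHODS = {
    "manifold": manifold_ranker,
    "manifold-sparse": manifold_sparse_ranker,
    "nearest": nearest_distance_ranker,
    "svm-binary": lambda t, l, rng=None, ctx=None: svm_ranker(
        t, l, strategy="binary", rng=rng, ctx=ctx
    ),
    "svm-one-class": lambda t, l, rng=None, ctx=None: svm_ranker(
        t, l, strategy="one_class", rng=rng, ctx=ctx
    ),
}


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-cell PR-AUCs and per-(method, query size) means."""

    results: pd.DataFrame  # columns: method, query_size, repeat, auc
    seed: int
    query_sizes: tuple[int, ...]
    repeats: int

    @property
    def summary(self) -> pd.DataFrame:
        return (
            self.results.groupby(["method", "query_size"], sort=True)["auc"]
            .mean()
            .reset_index()
            .rename(columns={"auc": "mean_auc"})
        )

    def mean_auc(self, method: str, query_size: int) -> float:
        s = self.summary
        row = s[(s.method == method) & (s.query_size == query_size)]
        return float(row.mean_auc.iloc[0])

    def write(self, path, summary_path=None) -> None:
        self.results.to_csv(path, sep="\t", index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, sep="\t", index=False)


def run_benchmark(
    table: FeatureTable,
    labels: LabelAssignment,
    query_sizes: list[int],
    repeats: int = 5,
    methods: list[str] | None = None,
    seed: int = 0,
) -> BenchmarkReport:
    """Query-subsampling benchmark over the registered ranking methods.

    For each repeat and query size, a query set is drawn uniformly without
    replacement from the known positives; every method ranks with the same
    queries, and PR-AUC is computed over the non-query samples with the
    remaining positives as truth.  Deterministic given ``seed``.
    """
    methods = methods or ["manifold"]
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; registered: {sorted(METHODS)}")
    pos_idx = np.flatnonzero(labels.positive)
    if max(query_sizes) > pos_idx.size:
        raise ValueError(
            f"largest query size {max(query_sizes)} exceeds {pos_idx.size} positives"
        )

    ctx: dict = {}
    truth = labels.positive
    rows = []
    root = np.random.SeedSequence(seed)
    for r, rep_seq in enumerate(root.spawn(repeats)):
        for qs, cell_seq in zip(query_sizes, rep_seq.spawn(len(query_sizes))):
            rng = np.random.default_rng(cell_seq)
            queries = rng.choice(pos_idx, size=qs, replace=False)
            q_labels = LabelAssignment(
                table.n,
                np.isin(np.arange(table.n), queries),
                np.zeros(table.n, dtype=bool),
            )
            for name in methods:
                scores = METHODS[name](
                    table, q_labels, rng=np.random.default_rng(cell_seq), ctx=ctx
                )
                auc = pr_curve(scores, truth, exclude=queries).auc
                rows.append(
                    {"method": name, "query_size": qs, "repeat": r, "auc": auc}
                )
    return BenchmarkReport(
        results=pd.DataFrame(rows),
        seed=seed,
        query_sizes=tuple(query_sizes),
        repeats=repeats,
    )
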