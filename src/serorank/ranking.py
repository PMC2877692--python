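"""Manifold-ranking solvers.

Given the normalized propagation operator ``L`` and an initial evidence
vector ``y`` (1 on query positives, 0 elsewhere), evidence is spread over the
graph by the fixed-point iteration

    f(t+1) = alpha * L @ f(t) + (1 - alpha) * y,      f(0) = y

with ``alpha`` in [0, 1) controlling how far query evidence propagates.
Because the spectral radius of ``L`` is at most 1, the iteration contracts
geometrically and converges to the closed form

    f* = (1 - alpha) * (I - alpha L)^{-1} @ y

which is computed here by a direct linear solve (never an explicit inverse).
The universal variant additionally propagates negative evidence:
``f* = A y+ + gamma A y- = A (y+ + gamma y-)`` with ``A = (1-alpha)(I-alpha L)^{-1}``
and ``gamma`` in (0, 1] damping the influence of known negatives (an
unlabeled point far from the positives is unlikely positive, but distance
from negatives carries weaker information).  ``gamma = 0`` is accepted as a
degenerate input reproducing positive-only ranking exactly.

Samples are ranked by decreasing ``f*``; queries float to the top and are
excluded again at evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .io import FeatureTable, LabelAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "RankingParams",
    "RankingResult",
    "rank_iterative",
    "rank_closed_form",
    "rank_universal",
    "rank",
    "tune_alpha",
]


@dataclass(frozen=True)
class RankingParams:
    """Solver configuration; defaults follow the positive-only use case."""

    alpha: float = 0.5
    gamma: float = 0.5
    tol: float = 1e-9
    max_iter: int = 10_000
    mode: str = "positive_only"  # or "universal"
    solver: str = "closed_form"  # or "iterative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.mode not in ("positive_only", "universal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.solver not in ("closed_form", "iterative"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass(frozen=True)
class RankingResult:
    scores: np.ndarray
    iterations: int
    converged: bool
    params: RankingParams

    @property
    def order(self) -> np.ndarray:
        """Sample indices by descending score; ties keep input order."""
        return np.argsort(-self.scores, kind="stable")


def _check_y(L: np.ndarray, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (L.shape[0],):
        raise ValueError(f"y has shape {y.shape}, expected ({L.shape[0]},)")
    return y


def rank_iterative(graph, y: np.ndarray, params: RankingParams | None = None) -> RankingResult:
    """Fixed-point propagation, iterated until the max-norm update < tol.

    Non-convergence within ``max_iter`` is flagged (``converged=False``) and
    logged, never silent.
    """
    params = params or RankingParams(solver="iterative")
    L = graph.L
    y = _check_y(L, y)
    a = params.alpha
    f = y.copy()
    for it in range(1, params.max_iter + 1):
        f_next = a * (L @ f) + (1.0 - a) * y
        delta = np.max(np.abs(f_next - f))
        f = f_next
        if delta < params.tol:
            return RankingResult(f, it, True, params)
    logger.warning("propagation hit max_iter=%d without converging", params.max_iter)
    return RankingResult(f, params.max_iter, False, params)


def rank_closed_form(graph, y: np.ndarray, params: RankingParams | None = None) -> RankingResult:
    """Exact fixed point ``(1-alpha)(I - alpha L)^{-1} y`` via linear solve.

    ``I - alpha L`` is symmetric positive definite for ``alpha < 1`` because
    the spectral radius of ``L`` is at most 1; a singular solve therefore
    indicates a broken operator and is surfaced, not masked.
    """
    params = params or RankingParams()
    L = graph.L
    y = _check_y(L, y)
    a = params.alpha
    A = np.eye(L.shape[0]) - a * L
    f = (1.0 - a) * scipy.linalg.solve(A, y, assume_a="pos")
    return RankingResult(f, 0, True, params)


def rank_universal(
    graph,
    y_plus: np.ndarray,
    y_minus: np.ndarray,
    params: RankingParams | None = None,
) -> RankingResult:
    """Positive + damped negative propagation in a single linear solve.

    ``f* = A y+ + gamma A y- = A (y+ + gamma y-)`` by linearity, so one solve
    on the combined evidence vector suffices.  With ``gamma = 0`` or an empty
    negative set the result is bitwise identical to positive-only ranking.
    """
    params = params or RankingParams(mode="universal")
    y_plus = np.asarray(y_plus, dtype=float)
    y_minus = np.asarray(y_minus, dtype=float)
    if (y_plus < 0).any():
        raise ValueError("y_plus must be non-negative")
    if (y_minus > 0).any():
        raise ValueError("y_minus must be non-positive")
    if ((y_plus != 0) & (y_minus != 0)).any():
        raise ValueError("positive and negative supports must be disjoint")
    combined = y_plus + params.gamma * y_minus
    result = rank_closed_form(graph, combined, params)
    return replace(result, params=params)


def rank(graph, labels: LabelAssignment, params: RankingParams | None = None) -> RankingResult:
    """Dispatch on mode and solver; the convenience entry point."""
    params = params or RankingParams()
    if params.mode == "universal":
        return rank_universal(graph, labels.y_plus, labels.y_minus, params)
    if params.solver == "iterative":
        return rank_iterative(graph, labels.y, params)
    return rank_closed_form(graph, labels.y, params)


def tune_alpha(
    table: FeatureTable,
    labels: LabelAssignment,
    grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Pick ``alpha`` by k-fold cross-validation over the labeled positives.

    The positives are split into ``folds`` folds; each fold in turn serves as
    the query set while the remaining positives are the held-out truth.  All
    non-query samples are ranked and scored by recall-precision AUC; the grid
    value with the highest mean AUC wins (ties go to the smaller ``alpha``).
    Grid values >= 1 are clamped to ``1 - 1e-6`` with a warning, since the
    closed form requires ``alpha < 1``.

    Returns ``(best_alpha, {alpha: mean_auc})``.
    """
    from .evaluation import pr_curve
    from .graph import build_affinity, estimate_sigma, normalize, pairwise_distances

    if grid is None:
        grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    clamped = grid >= 1.0
    if clamped.any():
        logger.warning("alpha grid values >= 1 clamped to 1 - 1e-6")
        grid = np.where(clamped, 1.0 - 1e-6, grid)

    pos_idx = np.flatnonzero(labels.positive)
    if pos_idx.size < folds:
        raise ValueError(
            f"{pos_idx.size} positives cannot fill {folds} folds; use fewer folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pos_idx)
    fold_sets = np.array_split(perm, folds)

    D = pairwise_distances(table)
    sigma = estimate_sigma(D)
    L = normalize(build_affinity(D, sigma))

    truth_all = labels.positive
    mean_auc: dict[float, float] = {}
    for a in grid:
        params = RankingParams(alpha=float(a))
        aucs = []
        for fold in fold_sets:
            y = np.zeros(table.n)
            y[fold] = 1.0
            scores = rank_closed_form(L, y, params).scores
            curve = pr_curve(scores, truth_all, exclude=fold)
            aucs.append(curve.auc)
        mean_auc[float(a)] = float(np.mean(aucs))
    best = min(mean_auc, key=lambda a: (-mean_auc[a], a))
    return best, mean_auc
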