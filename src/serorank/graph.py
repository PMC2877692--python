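"""Affinity-graph construction and symmetric normalization.

Samples become nodes of a fully connected weighted graph with Gaussian-kernel
edge weights ``W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` and ``W_ii = 0``.
The propagation operator is the symmetric normalization
``L = D^{-1/2} W D^{-1/2}`` whose spectral radius is at most 1, which is what
guarantees that ``I - alpha L`` is invertible for ``alpha < 1``.

The kernel bandwidth ``sigma`` defaults to the mean pairwise distance of the
dataset being ranked.  Normalization dampens but does not remove the effect
of ``sigma`` on the final ranking (the kernel is nonlinear in ``sigma``), so
it remains an explicit, overridable parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityGraph",
    "NormalizedGraph",
    "pairwise_distances",
    "estimate_sigma",
    "build_affinity",
    "normalize",
    "write_edge_list",
]


@dataclass(frozen=True)
class AffinityGraph:
    """Symmetric non-negative edge-weight matrix with zero diagonal."""

    W: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.diagonal(W).any():
            raise ValueError("W must have zero diagonal")
        if (W < 0).any() or (W > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)


@dataclass(frozen=True)
class NormalizedGraph:
    """``L = D^{-1/2} W D^{-1/2}``; zero rows for isolated nodes."""

    L: np.ndarray
    source: AffinityGraph

    @property
    def n(self) -> int:
        return self.L.shape[0]


def pairwise_distances(table: FeatureTable) -> np.ndarray:
    """Full Euclidean distance matrix (symmetric, zero diagonal)."""
    return squareform(pdist(table.X, metric="euclidean"))


def estimate_sigma(distances: np.ndarray) -> float:
    """Kernel bandwidth: mean of the ``n(n-1)/2`` pairwise distances.

    Duplicated points contribute zero distances and shrink the mean; that is
    deliberate — the bandwidth reflects the dataset actually being ranked.
    Raises if all points coincide (no scale to estimate).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to estimate sigma")
    sigma = float(d[np.triu_indices(n, k=1)].mean())
    if sigma <= 0.0:
        raise ValueError("degenerate dataset: all points identical, sigma = 0")
    return sigma


def build_affinity(distances: np.ndarray, sigma: float) -> AffinityGraph:
    """Gaussian-kernel weights from a distance matrix; diagonal forced to 0."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    d = np.asarray(distances, dtype=float)
    W = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(W, 0.0)
    return AffinityGraph(W, float(sigma))


def normalize(graph: AffinityGraph) -> NormalizedGraph:
    """Symmetric normalization ``D^{-1/2} W D^{-1/2}``.

    Isolated nodes (degree 0, possible after sparsification) get all-zero
    rows/columns: they neither receive nor emit propagation.
    """
    d = graph.degrees
    isolated = d <= 0
    if isolated.any():
        logger.warning("%d isolated node(s): zero rows in L", int(isolated.sum()))
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, d)))
    L = graph.W * inv_sqrt[:, None] * inv_sqrt[None, :]
    L = (L + L.T) / 2.0  # re-symmetrize against rounding
    return NormalizedGraph(L, graph)


def write_edge_list(graph: AffinityGraph, path) -> None:
    """Dump the upper-triangle nonzero edges as ``i<TAB>j<TAB>weight``."""
    W = graph.W
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(*np.nonzero(np.triu(W, k=1))):
            fh.write(f"{i}\t{j}\t{W[i, j]:.6g}\n")
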