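"""Seeded positive-unlabeled synthetic datasets.

Real use ranks a few hundred labeled secretory proteins against a ~50x
larger unlabeled proteome using 85 numeric features per protein.  These
generators reproduce that *statistical* structure at desk scale — a labeled
query minority, hidden positives clustered near them in feature space, a
large unlabeled background, heavy class imbalance — without pretending to
model real protein feature distributions.

Two layouts:

``gaussian_clusters``
    Positives and negatives drawn from two isotropic Gaussians whose centers
    sit ``separation * noise_sd`` apart along a random direction in m-dim
    space.  The simplest planted-structure testbed: any reasonable ranker
    should recover hidden positives when separation is large.

``curved_manifold``
    Positives along one arc and negatives along a parallel, interleaving arc
    (two-moons geometry) embedded in the first two coordinates, with
    isotropic noise in all m dimensions.  Points at one end of the positive
    arc are closer in Euclidean distance to the negative arc than to queries
    at the other end, so transductive propagation along the manifold beats
    plain nearest-distance ranking — the structure this method exists for.
    The arc scale grows with ``sqrt(m) * noise_sd`` so the geometry stays
    resolvable against the ambient noise, which accumulates across the m
    noise dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FeatureTable, LabelAssignment

__all__ = ["SyntheticSpec", "generate", "worked_example", "WORKED_EXAMPLE_COORDS"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Defaults mirror the target use case: 85 features and roughly 1:20
    positive:background imbalance, shrunk to desk scale (10 labeled queries,
    40 hidden positives, 200 negatives).
    """

    m: int = 85
    n_query: int = 10
    n_hidden_pos: int = 40
    n_neg: int = 200
    separation: float = 6.0
    noise_sd: float = 1.0
    layout: str = "gaussian_clusters"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_query < 1:
            raise ValueError("need at least one labeled query")
        if min(self.m, self.n_hidden_pos, self.n_neg) < 0:
            raise ValueError("counts must be non-negative")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.layout not in ("gaussian_clusters", "curved_manifold"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _gaussian_clusters(spec: SyntheticSpec, rng: np.random.Generator):
    n_pos = spec.n_query + spec.n_hidden_pos
    direction = rng.standard_normal(spec.m)
    direction /= np.linalg.norm(direction)
    c_neg = spec.separation * spec.noise_sd * direction
    pos = rng.normal(0.0, spec.noise_sd, size=(n_pos, spec.m))
    neg = c_neg + rng.normal(0.0, spec.noise_sd, size=(spec.n_neg, spec.m))
    return pos, neg


def _curved_manifold(spec: SyntheticSpec, rng: np.random.Generator):
    n_pos = spec.n_query + spec.n_hidden_pos
    scale = spec.separation * spec.noise_sd * np.sqrt(spec.m) / 4.0
    # two interleaving unit arcs (classic two-moons), scaled
    t_pos = rng.uniform(0.0, np.pi, size=n_pos)
    t_neg = rng.uniform(0.0, np.pi, size=spec.n_neg)
    pos2d = np.column_stack([np.cos(t_pos), np.sin(t_pos)])
    neg2d = np.column_stack([1.0 - np.cos(t_neg), 0.5 - np.sin(t_neg)])
    pos = np.zeros((n_pos, spec.m))
    neg = np.zeros((spec.n_neg, spec.m))
    pos[:, :2] = scale * pos2d
    neg[:, :2] = scale * neg2d
    pos += rng.normal(0.0, spec.noise_sd, size=pos.shape)
    neg += rng.normal(0.0, spec.noise_sd, size=neg.shape)
    return pos, neg


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, LabelAssignment, np.ndarray]:
    """Sample a dataset.

    Returns ``(table, labels, truth)`` where ``labels`` marks only the
    ``n_query`` labeled queries as positive (everything else unlabeled — the
    PU setting) and ``truth`` is 1 exactly on the *hidden* positives.
    Bitwise deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.layout == "gaussian_clusters":
        pos, neg = _gaussian_clusters(spec, rng)
    else:
        pos, neg = _curved_manifold(spec, rng)

    n_pos = pos.shape[0]
    X = np.vstack([pos, neg])
    n = X.shape[0]
    is_pos = np.zeros(n, dtype=bool)
    is_pos[:n_pos] = True

    perm = rng.permutation(n)
    X, is_pos = X[perm], is_pos[perm]

    pos_idx = np.flatnonzero(is_pos)
    queries = rng.choice(pos_idx, size=spec.n_query, replace=False)
    query_mask = np.zeros(n, dtype=bool)
    query_mask[queries] = True

    table = FeatureTable(tuple(f"s{i:04d}" for i in range(n)), X)
    labels = LabelAssignment(n, query_mask, np.zeros(n, dtype=bool))
    truth = (is_pos & ~query_mask).astype(int)
    return table, labels, truth


# Fixed 2-D toy used throughout the docs and tests: a tight cluster around
# the single query (t1) and a second cluster far away.
WORKED_EXAMPLE_COORDS = (
    ("t1", 0.0, 0.0),
    ("t2", 1.0, 0.0),
    ("t3", 0.0, 1.0),
    ("t4", 4.0, 4.0),
    ("t5", 5.0, 4.0),
    ("t6", 4.0, 5.0),
)


def worked_example() -> tuple[FeatureTable, LabelAssignment]:
    """The fixed 6-sample, 2-feature toy with ``t1`` as the only query."""
    ids = tuple(r[0] for r in WORKED_EXAMPLE_COORDS)
    X = np.array([[r[1], r[2]] for r in WORKED_EXAMPLE_COORDS])
    table = FeatureTable(ids, X)
    labels = LabelAssignment.from_sets(table, positives=["t1"])
    return table, labels
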