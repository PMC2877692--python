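# Methods

## Model

`serorank` ranks an unlabeled pool of samples (proteins as fixed-length
numeric feature vectors) by relevance to a small labeled positive set, the
positive-unlabeled setting in which curating negatives is impractical. The
ranker is transductive: all samples, labeled and unlabeled, enter a single
similarity graph, and query evidence is propagated over it.

With `n` samples in `R^m`, the affinity graph is the Gaussian kernel
`W_ij = exp(−‖x_i − x_j‖²/2σ²)` with zero diagonal, and the propagation
operator is the symmetric normalization `L = D^{−1/2} W D^{−1/2}`. Because
`L` is similar to the row-stochastic `D^{−1}W`, its spectrum lies in
`[−1, 1]`, so for `α ∈ [0, 1)` the iteration

    f(t+1) = α L f(t) + (1−α) y,    f(0) = y,   y_i = 1 on queries

is a contraction (ratio ≤ α in the 2-norm) with fixed point

    f* = (1−α) (I − αL)^{−1} y.

The closed form is the default solver — one symmetric positive-definite
solve; the iterative solver is kept for verification and very large `n`,
and the two agree to 1e-8 max-norm on random graphs (asserted in tests).
The leading `(1−α)` factor cannot change the ordering; it is retained so
both solvers produce identical values.

When a negative set exists, the universal variant propagates both
evidences in one solve: `f* = A(y⁺ + γ y⁻)` with `A = (1−α)(I − αL)^{−1}`,
`y⁻_i = −1` on negatives and `γ ∈ (0, 1]`. Negative evidence is damped
because distance from the positives is informative about not being
positive, while distance from negatives is much weaker information. `γ = 0`
is accepted as a degenerate input and reproduces positive-only scores
bitwise (the combined evidence vector is then bit-identical to `y⁺`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | propagation strength in `[0,1)`; 0 disables the graph entirely. 0.5 matches the cross-validated choice in the motivating application; `tune_alpha` reruns that 10-fold CV over the 0.1…0.9 grid on any dataset. |
| `sigma` | mean pairwise distance | kernel bandwidth (feature-space units), recomputed on the set actually ranked (i.e. after prefiltering). Overridable. Normalization dampens but does not cancel its effect — the kernel is nonlinear in σ — so the suite records ranking sensitivity rather than asserting invariance. |
| `gamma` | 0.5 | negative-evidence damping in `(0,1]`; the interval midpoint is the default since only the interval is prescribed by the method. |
| `b` | `max(5, ⌈log₂ n⌉)` | sparsification degree budget, bumped to parity feasibility (`n·b` must be even). A connectivity-motivated default: `log₂ n` neighbors keep a random geometric graph connected, floor of 5 guards small `n`. |
| `tol`, `max_iter` | 1e-9, 10000 | iterative-solver stopping rule; non-convergence is flagged and logged, never silent. |
| `filter_k` | 0 (off) | number of unlabeled samples dropped by the nearest-positive prefilter. |

## b-matching sparsification

Among symmetric binary patterns `P` with zero diagonal and exact row degree
`b`, the solver seeks the maximizer of `Σ W_ij P_ij`; retained edges keep
their Gaussian weight (`W′ = W ⊙ P`). Exact degree (rather than an upper
bound) is used: it is the canonical problem solved by belief-propagation
b-matching, and it guarantees `n·b/2` edges, so no node is orphaned by the
sparsifier itself.

The production solver is max-product loopy BP in the log domain: node `i`'s
message to `j` is minus the `b`-th best alternative among `i`'s other
neighbors; synchronous updates with damping 0.5, convergence at max message
change < 1e-6, cap 1000 iterations. Beliefs are decoded by mutual top-`b`
selection. Loopy BP carries no general convergence guarantee, so decode
failure (near-ties) or non-convergence triggers a fallback: small instances
(`n(n+b) ≤ 1200`) are solved *exactly* by the node-splitting reduction to
maximum-weight perfect matching (blossom algorithm via networkx); larger
instances use greedy decoding on beliefs with degree repair, plus a
degree-preserving 2-edge-swap polish when `n ≤ 60`. An independent
exhaustive branch-and-bound oracle (`bmatching_oracle`, `n ≤ 10`) certifies
optimality in the tests; ties there are broken toward the lexicographically
smallest edge set.

Why sparsify at all: with the global mean-distance bandwidth, local
distance differences are tiny relative to σ, so the dense graph is nearly
uniform and propagation barely distinguishes neighborhoods. Keeping only
each node's strongest consistent edges restores the local geometry; on the
curved-manifold synthetic data this is the difference between trailing and
beating the nearest-distance baseline.

## Prefilter

Samples are scored by Euclidean distance to their nearest labeled positive;
the `k` farthest unlabeled samples are dropped before graph construction
(positives are never dropped; known negatives are protected by default).
Distance ties break by input row order. σ is recomputed on the retained
subset, since the bandwidth should describe the dataset actually ranked.
On separable synthetic data, dropping half the unlabeled pool moves the
retained-set PR-AUC by under 0.05 (asserted in tests).

## Evaluation

PR-AUC is computed as average precision with step integration: sweep the
descending score order and average precision-at-rank over the true-positive
ranks. No trapezoidal interpolation — pointwise precision/recall is what
the definition gives, and the step form is reproducible without
interpolation conventions. Query samples are always excluded before the
curve is built; the task is retrieving positives the ranker was not told
about. One subtlety the tests encode: under a uniformly *random* ranking
the expectation of average precision is
`H_N/N·(1−(P−1)/(N−1)) + (P−1)/(N−1)` — slightly above the prevalence
`P/N`, with an `O(log N / N)` excess — so the random-baseline check
compares against this exact value rather than the asymptotic prevalence.

The benchmark protocol draws query subsets (e.g. 10/20/30) uniformly
without replacement from the known positives, runs every registered method
on identical queries, and averages PR-AUC over repeats (default 5).
Registered methods: dense manifold ranking, sparsified manifold ranking,
nearest-positive-distance, binary SVM (RBF, bandwidth tied to the graph σ,
`negative_multiple × q` sampled negatives — known negatives when present,
otherwise flagged use of unlabeled samples), and one-class SVM on the
queries alone, both ranking by signed decision value.

## Synthetic data

The generators reproduce the *statistical* structure of the application —
a labeled positive minority, hidden positives near them in feature space, a
~20× unlabeled background, 85 features — not real protein feature
distributions. Defaults: 10 queries, 40 hidden positives, 200 negatives,
`m = 85`, class centers `separation·noise_sd = 6` apart.

- `gaussian_clusters`: two isotropic Gaussians with centers 6 noise-sd
  apart along a random direction. The simplest planted structure; used for
  recovery and prefilter-robustness checks.
- `curved_manifold`: positives on one arc, negatives on a parallel
  interleaving arc (two-moons geometry) in the first two coordinates,
  isotropic noise in all `m`. The arc radius is `separation·noise_sd·√m/4`:
  ambient noise accumulates as `√m` across dimensions, so the curve scale
  must grow with `√m` to stay resolvable, and the `/4` factor places the
  task where manifold structure matters rather than where every method
  saturates. Points at one arc end are Euclidean-closer to the other class
  than to far-away queries, which is exactly the regime where transductive
  propagation beats nearest-distance ranking.

What passing these tests shows: the pipeline recovers planted structure
and exploits manifold geometry under controlled conditions. What it does
not show: performance on real protein feature tables, whose features are
correlated, heterogeneous in scale, and not Gaussian; results there depend
on feature quality and on σ/b choices, which is why both are exposed.

## Numerical and design choices

- `I − αL` is SPD for `α < 1` (spectral radius of `L` ≤ 1); the solver
  asserts positive-definiteness and surfaces failures rather than masking
  them. Isolated nodes (possible after sparsification) get zero rows in
  `L` and simply receive `(1−α)·y_i`.
- All orderings use stable sorts; score ties resolve by input row order, so
  outputs are deterministic and the full pipeline is bitwise reproducible
  given a seed (asserted end to end).
- Feature files are TSV by default (CSV by flag); missing or non-numeric
  cells are hard errors — silent imputation would corrupt the distance
  geometry everything depends on. An optional z-score flag standardizes
  features before distance computation (off by default; the motivating
  application's features are on comparable scales).
- Problem sizes in the test and acceptance runs (n = 250 synthetic
  samples, 50 seeded random graphs of n = 30, exhaustive certification up
  to n = 8) are chosen so every claim is recomputed from scratch in
  seconds while remaining large enough for the statistical assertions.

## Known limitations

- The ranking is transductive only: a new sample requires rebuilding the
  graph (no out-of-sample extension).
- Loopy BP optimality is certified only on small instances; on large
  graphs the fallback is a heuristic (exactness there is not required —
  sparsification only needs a heavy, feasible edge subset).
- The dense `O(n²)` distance matrix and `O(n³)` solve bound practical `n`
  to a few tens of thousands; the prefilter exists precisely to reach that
  regime.
- PR-AUC with very few positives is high-variance; the benchmark averages
  over repeats but single-cell values should be read with care.
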