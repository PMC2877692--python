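"""Straight-line reference computation for the 6-sample worked example.

Deliberately independent of the serorank package: explicit loops and a
direct linear solve only, so the committed fixture files act as an oracle
for the pipeline.  Re-running this script reproduces the files bitwise.

Usage: python tests/fixtures/generate_worked_example.py [out_dir]
"""

import math
import sys
from pathlib import Path

import numpy as np

# the fixed toy: one tight cluster around the single query t1, one far cluster
SAMPLES = [
    ("t1", 0.0, 0.0),  # the labeled positive
    ("t2", 1.0, 0.0),
    ("t3", 0.0, 1.0),
    ("t4", 4.0, 4.0),
    ("t5", 5.0, 4.0),
    ("t6", 4.0, 5.0),
]
ALPHA = 0.5

out_dir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path(__file__).parent
ids = [s[0] for s in SAMPLES]
X = [[s[1], s[2]] for s in SAMPLES]
n = len(X)

D = [[0.0] * n for _ in range(n)]
for i in range(n):
    for j in range(n):
        D[i][j] = math.sqrt((X[i][0] - X[j][0]) ** 2 + (X[i][1] - X[j][1]) ** 2)

pair_sum, pair_count = 0.0, 0
for i in range(n):
    for j in range(i + 1, n):
        pair_sum += D[i][j]
        pair_count += 1
sigma = pair_sum / pair_count

W = [[0.0] * n for _ in range(n)]
for i in range(n):
    for j in range(n):
        if i != j:
            W[i][j] = math.exp(-D[i][j] ** 2 / (2.0 * sigma ** 2))

deg = [sum(W[i]) for i in range(n)]
L = [[W[i][j] / math.sqrt(deg[i] * deg[j]) for j in range(n)] for i in range(n)]

y = [1.0] + [0.0] * (n - 1)
A = np.eye(n) - ALPHA * np.array(L)
f_star = (1.0 - ALPHA) * np.linalg.solve(A, np.array(y))


def write_matrix(name, M):
    with open(out_dir / name, "w", encoding="utf-8") as fh:
        for row in M:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


with open(out_dir / "worked_features.tsv", "w", encoding="utf-8") as fh:
    for sid, a, b in SAMPLES:
        fh.write(f"{sid}\t{a!r}\t{b!r}\n")
with open(out_dir / "worked_labels.tsv", "w", encoding="utf-8") as fh:
    fh.write("t1\tpositive\n")
with open(out_dir / "worked_sigma.txt", "w", encoding="utf-8") as fh:
    fh.write(repr(sigma) + "\n")
write_matrix("worked_distances.tsv", D)
write_matrix("worked_affinity.tsv", W)
write_matrix("worked_normalized.tsv", L)
write_matrix("worked_scores.tsv", [[v] for v in f_star])
print(f"wrote worked-example fixtures to {out_dir} (sigma={sigma:.6f})")
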