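"""Cross-validated selection of the propagation strength alpha.

Splits the labeled positives into folds, uses each fold as queries and the
rest as held-out truth, and picks the alpha with the best mean PR-AUC over
the 0.1..0.9 grid.
"""

from serorank import generate, tune_alpha
from serorank.synthetic import SyntheticSpec

table, labels, _ = generate(
    SyntheticSpec(m=20, n_query=30, n_hidden_pos=0, n_neg=150, seed=2)
)
best, table_auc = tune_alpha(table, labels, folds=10, seed=0)

print("alpha   mean PR-AUC (10-fold CV)")
for alpha in sorted(table_auc):
    marker = "  <- selected" if alpha == best else ""
    print(f"{alpha:.1f}     {table_auc[alpha]:.4f}{marker}")
print(
    "\nLarger alpha propagates query evidence further over the graph;"
    "\nthe cross-validated optimum balances spread against dilution."
)
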