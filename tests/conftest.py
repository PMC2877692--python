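import numpy as np
import pytest

from serorank import FeatureTable, LabelAssignment, build_affinity
from serorank.synthetic import worked_example

FIXTURES = __import__("pathlib").Path(__file__).parent / "fixtures"


@pytest.fixture
def toy_table():
    table, labels = worked_example()
    return table, labels


@pytest.fixture
def fixtures_dir():
    return FIXTURES


def random_affinity(n: int, seed: int) -> "build_affinity":
    """Seeded random affinity graph: symmetric weights in (0, 1], zero diagonal."""
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.1, 3.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return build_affinity(d, 1.0)


def random_table(n: int, m: int, seed: int) -> FeatureTable:
    rng = np.random.default_rng(seed)
    return FeatureTable(
        tuple(f"s{i:03d}" for i in range(n)), rng.standard_normal((n, m))
    )


def labels_for(table: FeatureTable, positives) -> LabelAssignment:
    mask = np.zeros(table.n, dtype=bool)
    mask[list(positives)] = True
    return LabelAssignment(table.n, mask, np.zeros(table.n, dtype=bool))
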