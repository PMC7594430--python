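import numpy as np
import pytest

from consensusde.io_model import (
    CohortConfig,
    CountMatrix,
    group_labels,
    pair_index,
)
from consensusde.synthetic import simulate_case_control, simulate_twins


def random_count_matrix(rng: np.random.Generator, g: int = 20, s: int = 6) -> CountMatrix:
    return CountMatrix(
        [f"t{i}" for i in range(g)],
        [f"g{i // 2}" for i in range(g)],
        rng.integers(200, 20000, size=g),
        rng.integers(0, 500, size=(g, s)),
        [f"s{j}" for j in range(s)],
    )


@pytest.fixture(scope="session")
def small_cc():
    """A small case-control cohort with spiked DE, shared across tests."""
    cfg = CohortConfig(n_transcripts=300, de_fraction=0.1, seed=42)
    cm, rows, truth = simulate_case_control(cfg, 42)
    return cm, rows, truth, group_labels(rows, cm.sample_ids), cfg


@pytest.fixture(scope="session")
def small_twins():
    cfg = CohortConfig(n_transcripts=300, de_fraction=0.1, seed=43)
    cm, rows, truth = simulate_twins(cfg, 43)
    return cm, rows, truth, group_labels(rows, cm.sample_ids), pair_index(rows, cm.sample_ids), cfg
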