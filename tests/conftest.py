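import numpy as np
import pandas as pd
import pytest

from clutchsig import ProbeMatrix, SimConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic experiment with ground truth (shared, read-only)."""
    cfg = SimConfig(n_genes=2000, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    matrix, annotation, sheet, truth = small_dataset
    return run_pipeline(matrix, annotation), truth


@pytest.fixture()
def toy_matrix():
    """4 probes x 4 samples, 2 clutches, hand-checkable values."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 5.0, 2.0, 8.0],
            "a2": [2.0, 6.0, 2.0, 8.5],
            "b1": [1.5, 5.5, 2.0, 9.0],
            "b2": [2.5, 6.5, 2.0, 9.5],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    meta = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return ProbeMatrix(values, meta)
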