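import numpy as np
import pandas as pd
import pytest

from leafmix.simulate import ReferenceSimConfig, simulate_reference


@pytest.fixture(scope="session")
def small_reference():
    """5-type, 600-gene reference used across unit tests."""
    cfg = ReferenceSimConfig(
        n_cell_types=5,
        cells_per_type=(80,) * 5,
        n_genes=600,
        markers_per_type=20,
        marker_fold_change=4.0,
        baseline_mean=0.3,
        dispersion=0.4,
        seed=11,
    )
    return simulate_reference(cfg)


@pytest.fixture(scope="session")
def small_signature(small_reference):
    from leafmix.signature import build_signature

    return build_signature(
        small_reference.counts, small_reference.labels, markers_range=(20, 40)
    )


@pytest.fixture
def orthogonal_signature():
    """Two types with disjoint exclusive marker blocks (orthogonal columns)."""
    genes = [f"g{i}" for i in range(12)]
    values = pd.DataFrame(
        {"alpha": [10.0] * 6 + [0.0] * 6, "beta": [0.0] * 6 + [10.0] * 6},
        index=genes,
    )
    return values


@pytest.fixture
def rng():
    return np.random.default_rng(0)
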