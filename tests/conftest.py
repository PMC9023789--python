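import numpy as np
import pandas as pd
import pytest

from celldiv.composition import CompositionMatrix, count_composition


@pytest.fixture
def small_cells() -> pd.DataFrame:
    """6 cells in one sample: T,T,T,B,B,NK."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "sample_id": ["S1"] * 6,
            "cell_type": ["T", "T", "T", "B", "B", "NK"],
        }
    )


@pytest.fixture
def two_sample_cells() -> pd.DataFrame:
    rows = [("S1", "T")] * 3 + [("S1", "B")] * 2 + [("S1", "NK")] + [("S2", "T")] * 4
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(rows))],
            "sample_id": [r[0] for r in rows],
            "cell_type": [r[1] for r in rows],
        }
    )


@pytest.fixture
def lineage_hierarchy() -> dict:
    return {"T": "Lymph", "B": "Lymph", "NK": "Lymph", "Mono": "Myel", "DC": "Myel"}


@pytest.fixture
def comp_small(small_cells) -> CompositionMatrix:
    return count_composition(small_cells)


def random_simplex(rng: np.random.Generator, k: int) -> np.ndarray:
    """Independent simplex sampler for property tests (uniform Dirichlet)."""
    x = rng.dirichlet(np.ones(k))
    return x / x.sum()
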