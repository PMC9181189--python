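import numpy as np
import pandas as pd
import pytest

from percepsim.chem_io import PairFeatureTable, standardize_molecule


@pytest.fixture(scope="session")
def aspirin():
    return standardize_molecule("CC(=O)Oc1ccccc1C(=O)O", "aspirin")


@pytest.fixture(scope="session")
def naphthalene():
    return standardize_molecule("c1ccc2ccccc2c1", "naphthalene")


@pytest.fixture()
def vote_table():
    """Small hand-written vote table with both features."""
    df = pd.DataFrame(
        {
            "pair_id": ["p1", "p2", "p3", "p4"],
            "tXT": [0.9, 0.2, 0.75, 0.4],
            "tCS": [1.8, 0.5, 1.2, 1.5],
            "n_similar": [20, 1, 15, 8],
            "n_total": [21, 21, 21, 21],
        }
    )
    return PairFeatureTable(df=df, dialect="votes")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
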