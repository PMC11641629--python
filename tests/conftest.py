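import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

#: Small molecules (<= 8 heavy atoms) for exhaustive-oracle comparisons.
SMALL_MOLECULES = [
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CCO", "CCN", "CC(C)O", "CCCO",
    "CC=O", "CC(C)=O", "CC(=O)O", "C=CC", "C#CC", "CCCl", "CCBr",
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "C1CCCCC1", "C1CCCC1", "C1CC1",
    "CC#N", "CCOC", "c1ccncc1", "CC(=O)OC", "CCS", "C=O", "CCC(C)O",
    "c1ccsc1",
]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_molecules():
    return list(SMALL_MOLECULES)
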