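import numpy as np
import pytest

from flspace import fixtures as fx
from flspace.mqn import MQN_NAMES, compute_mqn
from flspace.mqn_index import MQNNeighborIndex

DECOY_SEED = 20140522  # publication date of the underlying study, as a stable seed
N_DECOYS = 10_000


@pytest.fixture(scope="session")
def curated():
    return fx.curated_fragrances()


@pytest.fixture(scope="session")
def curated_records(curated):
    return curated.records


@pytest.fixture(scope="session")
def decoys():
    """10,000 generated fragrance-like decoys, shared across the suite."""
    return fx.generate_decoys(N_DECOYS, seed=DECOY_SEED)


@pytest.fixture(scope="session")
def decoy_mqns(decoys):
    return np.vstack([compute_mqn(r.mol) for r in decoys])


@pytest.fixture(scope="session")
def decoy_index(decoys):
    """Decoys split over two registered databases (a third overlaps both)."""
    assignments = {}
    for i, rec in enumerate(decoys):
        dbs = ["dbA"] if i % 2 == 0 else ["dbB"]
        if i % 7 == 0:
            dbs.append("dbB")
        assignments[rec.id] = dbs
    return MQNNeighborIndex().fit(decoys, assignments)
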