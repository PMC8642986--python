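import numpy as np
import pytest

from barcodekit import synthetic_data as sd
from barcodekit.fixtures import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def small_community():
    """One modest 4-marker community reused by several integration tests."""
    cfg = sd.SimConfig(
        seed=42,
        n_species=8,
        n_hybrids=1,
        markers=[
            sd.MarkerModel("rbcL", 200, rate=0.25, recovery=0.99),
            sd.MarkerModel("ITS2", 240, rate=1.0, recovery=0.9, genome="nuclear"),
            sd.MarkerModel("matK", 260, rate=0.6, recovery=0.8),
            sd.MarkerModel("trnH-psbA", 300, rate=0.8, recovery=0.8, indel_rate=4.0),
        ],
    )
    return sd.simulate_community(cfg)


def random_labeled_matrix(rng, n_species=4, max_per_species=4):
    """Random symmetric distance matrix with species labels, for enumeration
    oracles (gap tables, partitions)."""
    from barcodekit.distmat import DistanceMatrix
    from barcodekit.seq_io import SpecimenRecord

    ids, specimens = [], []
    for s in range(n_species):
        k = int(rng.integers(1, max_per_species + 1))
        for i in range(k):
            sid = f"sp{s}_{i}"
            ids.append(sid)
            specimens.append(SpecimenRecord(specimen_id=sid, species=f"Sp{s}", site_id="X"))
    n = len(ids)
    d = np.round(rng.random((n, n)), 3)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, np.full((n, n), 100)), specimens
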