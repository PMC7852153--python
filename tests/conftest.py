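import pytest

from lncsuite.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study, shared across tests (seed fixed)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def rpkm(dataset):
    from lncsuite.diffexpr import compute_rpkm

    return compute_rpkm(dataset.counts, dataset.lengths)
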