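import pytest

from isocall.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study at seed 1, shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_calls(default_dataset):
    from isocall.classify import classify_all

    calls, tally = classify_all(default_dataset.queries, default_dataset.annotation)
    return calls, tally
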