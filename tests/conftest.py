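import pytest

from respibreath import breathing, features, signal_io, synthetic_data


@pytest.fixture(scope="session")
def tiny_recording():
    """One-trial (60 s quiet + 60 s talk) sitting recording, seeded."""
    cfg = synthetic_data.SimulationConfig(seed=5, n_trials=1, block_duration=60.0)
    return synthetic_data.simulate_recording(cfg)


@pytest.fixture(scope="session")
def tiny_resistance(tiny_recording):
    return signal_io.voltage_to_resistance(tiny_recording)


@pytest.fixture(scope="session")
def tiny_events(tiny_resistance):
    return breathing.detect_all(tiny_resistance)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_resistance, tiny_events):
    """Labelled feature matrix of the tiny recording (reused across tests)."""
    return features.feature_matrix(tiny_events, tiny_resistance)
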