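import numpy as np
import pytest

import gmfwp as g


@pytest.fixture(scope="session")
def curves():
    return g.load_curves()


@pytest.fixture(scope="session")
def fixture_b():
    return g.gen_measurement_fixture("B")


@pytest.fixture(scope="session")
def fixture_c():
    return g.gen_measurement_fixture("C")


@pytest.fixture()
def tone_record():
    """Single-axis 1 kHz cosine at sqrt(2) x RL limit amplitude (index 100%)."""
    A = np.sqrt(2.0) * g.limit_value("RL_B", 1000.0)
    spec = g.SequenceSpec(kind="tone", fundamental=1000.0, sample_rate=50_000.0,
                          amplitude_at_reference=A, repetitions=5)
    return g.gen_waveform(spec)
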