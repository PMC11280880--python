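import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_stream():
    """A moderate default synthetic stream (200 episodes/class, seed 17)."""
    from harssl.synthetic import SignalSpec, generate_signal

    return generate_signal(SignalSpec(episodes_per_class=200, seed=17))


@pytest.fixture(scope="session")
def default_features(default_stream):
    """Featurised version of ``default_stream`` under default preprocessing."""
    from harssl import ActivitySSL, SSLConfig

    m = ActivitySSL.from_raw(default_stream, SSLConfig(random_seed=17))
    return m.features, m.true_labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
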