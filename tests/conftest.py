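import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_proteome():
    """A deterministic planted proteome shared across tests."""
    from agpkit.synthetic_data import ProteomeSpec, generate_proteome

    return generate_proteome(ProteomeSpec(seed=11))
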