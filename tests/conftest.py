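import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ancestor():
    from aninull import generate_ancestor

    return generate_ancestor(50_000, 0.42, seed=7, label="anc")
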