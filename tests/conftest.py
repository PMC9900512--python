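import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from bycatchrisk import demo_world, estimate, simulate  # noqa: E402


@pytest.fixture(scope="session")
def demo_bundle():
    """One seeded synthetic run shared by the slower integration tests."""
    return simulate(demo_world(seed=1))


@pytest.fixture(scope="session")
def demo_result(demo_bundle):
    b = demo_bundle
    return estimate(b.bycatch, b.abundance, b.effort, b.world.membership)
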