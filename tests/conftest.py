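import hypothesis
import pytest

from warburglp import ModelSpec

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=200, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def low_cost_spec() -> ModelSpec:
    """Cheap respiration (alpha3=10), unlimited substrate, budget 200."""
    return ModelSpec.from_values(alpha3=10.0)


@pytest.fixture
def high_cost_spec() -> ModelSpec:
    """Expensive respiration (alpha3=50), unlimited substrate, budget 200."""
    return ModelSpec.from_values(alpha3=50.0)
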