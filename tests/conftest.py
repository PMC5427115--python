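import pytest

from strepflux import ToyModelSpec, generate_toy_model

from helpers import chain_model


@pytest.fixture
def toy():
    """Default planted toy model with its analytic ground truth."""
    return generate_toy_model(ToyModelSpec())


@pytest.fixture
def chain():
    """Linear three-reaction chain with optimum 10 (bound-limited)."""
    return chain_model(uptake=10.0)
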