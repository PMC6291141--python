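import numpy as np
import pytest

from hiergrn import (
    StudyDesign,
    generate_planted_network,
    simulate_expression,
)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def tiny_truth():
    """1 superhub -> 3 hubs -> 15 terminals, noiseless."""
    return generate_planted_network(
        1, (3, 3), (5, 5), 0, seed=7, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def tiny_expr(tiny_truth, design):
    return simulate_expression(tiny_truth, design, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    """Miniature noisy study: 2 superhubs over a 5-hub pool plus background."""
    return generate_planted_network(
        2, (3, 3), (25, 30), 2000, seed=42, n_hubs=5, n_independent=120,
        noise_sd=0.3,
    )


@pytest.fixture(scope="session")
def small_expr(small_truth, design):
    return simulate_expression(small_truth, design, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
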