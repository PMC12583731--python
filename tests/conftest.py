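import numpy as np
import pytest

from shiftselect.synthetic import SyntheticConfig, make_benchmark_case

#: Desk-scale study conditions for unit tests (the full 5,000-environment
#: benchmark is exercised by the acceptance suite).
SMALL = SyntheticConfig(n_runs=2, n_frames=5, molecules_per_frame=10)


@pytest.fixture(scope="session")
def small_case():
    """200-environment planted H-bond benchmark."""
    return make_benchmark_case("planted_hbond", seed=11, config=SMALL)


@pytest.fixture(scope="session")
def small_null_case():
    return make_benchmark_case("null", seed=11, config=SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
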