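import numpy as np
import pytest

from reinstate.design import default_design, make_design


@pytest.fixture(scope="session")
def design():
    """Full-size default session design."""
    return default_design()


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down session (4 study pairs of 5-trial blocks, 3 test pairs)."""
    return make_design(
        n_study_pairs=4, study_trials=5, n_test_pairs=3, test_trials=5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
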