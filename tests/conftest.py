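import numpy as np
import pytest

import gpcount as gp


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Canonical synthetic fixture suite, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    gp.make_fixture_suite(out, seed=0)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_group_data():
    """Moderate two-group matrix with known truth (20% DE at LFC 1.5)."""
    counts, design, sf, truth = gp.simulate_two_group(
        80, 50, seed=7, theta=0.3, frac_de=0.2, lfc=1.5
    )
    return counts, design, sf, truth
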