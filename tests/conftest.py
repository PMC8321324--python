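import numpy as np
import pytest

import deglare as dg

DPP = 45.0 / 400.0  # fundus-camera calibration: 45 deg field over 400 px


@pytest.fixture(scope="session")
def star():
    """Canonical 400x400 full-contrast 32-spoke Siemens star."""
    return dg.siemens_star()


@pytest.fixture(scope="session")
def small_star():
    """Small star for fast RL convergence checks."""
    return dg.siemens_star(dg.StarSpec(size=128, n_spokes=16))


@pytest.fixture(scope="session")
def niqe_model():
    """Quality model trained on the default balanced reference corpus."""
    references, _ = dg.make_fixture_set(5, 1, seed=1)
    return dg.train_niqe(references)


@pytest.fixture(scope="session")
def degraded_stars(star):
    """Star degraded at the induced angles of the recovery experiment."""
    return {alpha: dg.degrade(star, alpha) for alpha in (1.0, 2.0, 5.0, 6.0)}
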