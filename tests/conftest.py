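import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from historoi import RoiDetector
from historoi.fixtures import FixtureSpec, fixture_suite

TRAIN_SEED = 101
HELDOUT_SEED = 202


@pytest.fixture(scope="session")
def training_suite():
    """20 default synthetic fields used for learning."""
    return fixture_suite(20, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_suite():
    """20 default synthetic fields never seen during learning."""
    return fixture_suite(20, seed=HELDOUT_SEED)


@pytest.fixture(scope="session")
def trained_detector(training_suite):
    """The full two-stage learner run once on the training suite."""
    det = RoiDetector()
    det.fit([img for img, _ in training_suite],
            [mask for _, mask in training_suite])
    return det


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fixture():
    """One 96x96 single-islet field plus mask, for cheap pipeline tests."""
    spec = FixtureSpec(width=96, height=96, n_islets=1,
                       islet_radius_range=(14, 18), seed=5)
    from historoi.fixtures import generate_fixture

    return generate_fixture(spec)
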