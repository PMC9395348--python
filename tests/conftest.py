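"""Shared fixtures.

The trained networks are expensive (minutes each on one CPU), so they are
session-scoped and shared between the acceptance tests and the empirical
property tests.  Everything is seeded; the suite is deterministic.
"""

import numpy as np
import pytest

from glottikit.protocols import make_clips, train_desk_segnet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_net_fl1():
    """Depth-4, f_L=1, no-skip reference net trained on 510 clean frames."""
    model, history = train_desk_segnet(seed=0)
    return model, history


@pytest.fixture(scope="session")
def desk_net_fl16():
    model, history = train_desk_segnet(seed=0, latent_channels=16)
    return model, history


@pytest.fixture(scope="session")
def desk_net_d3():
    """Depth-3 variant (16x8 latent) used by the waveform-proxy experiment."""
    model, history = train_desk_segnet(seed=0, depth=3, epochs=6)
    return model, history


@pytest.fixture(scope="session")
def desk_test_clips():
    """Held-out clean clips never seen during training (seed 999)."""
    return make_clips(4, 999)
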