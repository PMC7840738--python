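import numpy as np
import pytest

import msmodes as mm


@pytest.fixture(scope="session")
def timebase():
    return mm.TimeBase(dt=0.01, k=5, T=0)


@pytest.fixture(scope="session")
def planted_gt(timebase):
    """Default planted ground truth: 3 complex modes (one behavior-coupled
    slow mode at 1.1 s / 0.17 Hz) + 1 real mode; 20 spike and 30 LFP
    channels, 3 behavior dimensions."""
    return mm.build_model(mm.default_mode_specs(), n_c=20, n_y=30, n_b=3,
                          timebase=timebase, seed=11)


@pytest.fixture(scope="session")
def planted_ds(planted_gt):
    """A moderate simulated recording (200 s) shared by several tests."""
    return mm.simulate(planted_gt, T=20_000, seed=7)


@pytest.fixture(scope="session")
def small_ds(planted_gt):
    return mm.simulate(planted_gt, T=2_000, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
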