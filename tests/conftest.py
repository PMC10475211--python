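"""Shared synthetic fixtures.

Everything is generated at test time from fixed seeds; the heavier
simulations are session-scoped so several test modules can reuse them.
"""

import numpy as np
import pytest

from scnsync import (
    OneCommunityParams,
    RenderOptions,
    TwoCommunityParams,
    make_slice_fixture,
)
from scnsync.traces import process_traces


@pytest.fixture(scope="session")
def noisy_slice():
    """A rendered one-community slice at moderate coupling and unit noise."""
    params = OneCommunityParams(
        n_oscillators=200, K=2.0, D=1.0, n_cycles=8, seed=7, init_phase_sd=0.5
    )
    fixture = make_slice_fixture(params)
    series = process_traces(fixture.trace_matrix())
    return params, fixture, series


@pytest.fixture(scope="session")
def noiseless_slice():
    """Deterministic phases (D=0), clean rendering: exact ground truth."""
    params = OneCommunityParams(
        n_oscillators=100, K=0.5, D=0.0, n_cycles=6, seed=1, init_phase_sd=0.8
    )
    fixture = make_slice_fixture(params, opts=RenderOptions(noise_sd=0.0))
    series = process_traces(fixture.trace_matrix())
    return params, fixture, series


@pytest.fixture(scope="session")
def antiphase_slice():
    """Two internally synced communities held in antiphase by repulsion."""
    params = TwoCommunityParams(
        n_per_community=60,
        K1=4.0,
        K2=4.0,
        L1=-2.0,
        L2=-2.0,
        D=1.0,
        n_cycles=6,
        seed=11,
        init_phase_sd=0.4,
        init_phase_offset=np.pi,
    )
    fixture = make_slice_fixture(params)
    return params, fixture
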