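import numpy as np
import pytest

from thermofmri.core import BoldSeries
from thermofmri.phantom import (
    HRFParams,
    StimEvent,
    StimulusProtocol,
    build_stimulus_protocol,
    build_synthetic_atlas,
)


@pytest.fixture(scope="session")
def hrf():
    return HRFParams()


@pytest.fixture(scope="session")
def small_atlas():
    """16x16x6 grid, 8 structures: large enough for parcel statistics,
    small enough for exhaustive checks."""
    return build_synthetic_atlas((16, 16, 6), 8, seed=3)


@pytest.fixture(scope="session")
def protocol_one_set():
    return build_stimulus_protocol(n_sets=1, seed=0)


@pytest.fixture(scope="session")
def protocol_three_sets():
    return build_stimulus_protocol(n_sets=3, seed=0)


def make_series(data, tr=2.0, voxel_size=(0.391, 0.391, 1.0), mask=None, t0=0.0):
    return BoldSeries(
        data=np.asarray(data, dtype=float),
        tr=tr,
        voxel_size=voxel_size,
        brain_mask=mask,
        t0=t0,
    )


def single_temperature_protocol(temperature=54, onsets=(120.0, 360.0, 600.0)):
    """A protocol containing only events of one temperature."""
    events = [
        StimEvent(onset=o, ramp=5.0, plateau=15.0, temperature=temperature, set_index=0)
        for o in onsets
    ]
    return StimulusProtocol(events=events)
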