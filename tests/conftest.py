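import dataclasses

import numpy as np
import pytest

from mwct.core import LimbPotentialRecording, WeightTern
from mwct.synth import SyntheticParams, generate_recording, lead_ii_peak_to_peak


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_recording():
    """Tiny handmade recording for arithmetic checks."""
    return LimbPotentialRecording(
        phi_L=np.array([3.0, 1.0, 0.0, 2.0]),
        phi_R=np.array([0.0, 1.0, 0.5, 2.0]),
        phi_F=np.array([0.0, 1.0, 1.0, 2.0]),
        sample_rate=4.0,
        subject_id="toy",
    )


@pytest.fixture
def fast_params():
    """Short, low-rate synthetic parameters for quick GA tests."""
    return SyntheticParams(
        duration=2.5,
        sample_rate=400.0,
        planted_tern=WeightTern(0.25, 0.25, 0.5),
        noise_sd=0.0,
        baseline_drift_amplitude=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_params(fast_params):
    """Same excerpt with noise at 1% of the lead II peak-to-peak."""
    return dataclasses.replace(
        fast_params, noise_sd=0.01 * lead_ii_peak_to_peak(fast_params)
    )


@pytest.fixture
def fast_recording(fast_params):
    rec, tern = generate_recording(fast_params)
    return rec, tern
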