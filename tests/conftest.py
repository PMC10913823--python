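import numpy as np
import pytest

from nirsfc.montage import default_montage, default_roi_map
from nirsfc.recording import Annotation, RawRecording
from nirsfc.simulate import GroundTruthSpec, default_condition_specs, simulate_participant


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def roi_map():
    return default_roi_map()


@pytest.fixture(scope="session")
def realistic_participant():
    """One participant with both conditions under the default (realistic) spec."""
    return simulate_participant(default_condition_specs(), seed=11)


@pytest.fixture(scope="session")
def clean_participant():
    """Nuisance-free participant: channels carry pure latent neural content."""
    specs = {"preferred": GroundTruthSpec().noise_free()}
    return simulate_participant(specs, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_raw(intensity, fs=25.0, label="preferred"):
    """Minimal raw recording around a given (n_ch, 2, T) intensity array."""
    intensity = np.asarray(intensity, dtype=float)
    n_t = intensity.shape[2]
    return RawRecording(
        intensity=intensity,
        accelerometer=np.zeros((3, n_t)),
        annotations=[Annotation(0.0, n_t / fs, label)],
        sampling_rate_hz=fs,
    )
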