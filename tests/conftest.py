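import numpy as np
import pytest

from eegsq.features import asymmetry_features, default_bands
from eegsq.montage import make_montage
from eegsq.preprocess import filter_resample, segment_epochs
from eegsq.synth import ParadigmConfig, default_signatures, simulate_session

#: Compact 17-electrode layout (8 homologous pairs + Cz) spanning all five
#: scalp regions; used wherever the full 62-channel montage is not the point.
TOY_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "FC3", "FC4",
    "C3", "C4", "T7", "T8", "P3", "P4", "O1", "O2", "Cz",
)


@pytest.fixture(scope="session")
def toy_montage():
    return make_montage(channels=TOY_CHANNELS)


@pytest.fixture(scope="session")
def small_recording(toy_montage):
    """A compact session: 3 classes x 3 sounds x 5 repetitions of 5-s stimuli."""
    paradigm = ParadigmConfig(n_repetitions=5, seed=1)
    return simulate_session(toy_montage, paradigm, default_signatures())


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    rec = filter_resample(small_recording)
    return segment_epochs(rec, epoch_duration=1.0, stimulus_duration=5.0)


@pytest.fixture(scope="session")
def small_features(small_epochs):
    return asymmetry_features(
        small_epochs, default_bands(), bases={"PSD", "Hjorth", "DE"}, modes={"DASM", "RASM"}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
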