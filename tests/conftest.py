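import numpy as np
import pytest

from abrgp import StimulusSpec, SubjectProfile
from abrgp.preprocess import EpochEnsemble, accumulate
from abrgp.simulate import FS_HZ, N_SAMPLES, band_limited_noise, wave_v_template


@pytest.fixture
def flat30_profile():
    """Subject with 30 dB HL thresholds at all four frequencies."""
    return SubjectProfile(
        thresholds={500.0: 30.0, 1000.0: 30.0, 2000.0: 30.0, 4000.0: 30.0},
        noise_rms=5.0,
    )


@pytest.fixture
def stim70():
    return StimulusSpec(level=70.0, frequency=1000.0)


def make_noise_ensemble(
    n_epochs: int,
    rms: float,
    seed: int,
    amplitude: float = 0.0,
    peak_ms: float = 8.0,
    trough_lag_ms: float = 2.0,
    frequency: float = 1000.0,
) -> EpochEnsemble:
    """Ensemble of band-limited-noise epochs with an optional injected wave V."""
    rng = np.random.default_rng(seed)
    epochs = band_limited_noise(n_epochs, N_SAMPLES, rms, FS_HZ, rng)
    if amplitude > 0:
        epochs = epochs + wave_v_template(amplitude, peak_ms, trough_lag_ms)
    ens = EpochEnsemble(StimulusSpec(level=70.0, frequency=frequency))
    accumulate(ens, epochs)
    return ens
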