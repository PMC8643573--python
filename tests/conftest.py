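import numpy as np
import pytest

from mrcplab.model import Montage, TrialEpoch, epoch_times
from mrcplab.synth import mrcp_template


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage()


def make_template_epoch(
    peak_time_s: float = 0.3,
    ns1: float = -3.0,
    ns2: float = -12.0,
    peak_uv: float = -16.0,
    rebound: float = 3.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    trial_index: int = 0,
) -> TrialEpoch:
    """Onset-locked epoch carrying the analytic MRCP template on every
    channel (plus optional white noise) — the oracle input for feature
    tests."""
    times = epoch_times()
    wave = mrcp_template(times, peak_time_s, ns1, ns2, peak_uv, rebound)
    eeg = np.tile(wave, (17, 1))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        eeg = eeg + noise_sd * rng.standard_normal(eeg.shape)
    return TrialEpoch(subject_id="S", trial_index=trial_index,
                      onset_time_s=0.0, eeg=eeg, times=times)


@pytest.fixture
def template_epoch() -> TrialEpoch:
    return make_template_epoch()
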