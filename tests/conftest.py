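import pytest

from gyrocg import SubjectParams, simulate_subject
from gyrocg.synth import subject_noise_for_snr

FS = 800.0


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free subject at the default delay means (no jitter, no
    respiration): every waveform extremum sits exactly on its event."""
    p = SubjectParams(seed=11, hr_sd_within=0.0, delay_jitter_ms=0.0,
                      resp_depth=0.0)
    return simulate_subject(p, duration=20.0, fs=FS)


@pytest.fixture(scope="session")
def noisy_sim():
    """One subject at 10 dB amplitude SNR, 60 s."""
    p = SubjectParams(seed=21, **subject_noise_for_snr(10.0))
    return simulate_subject(p, duration=60.0, fs=FS)
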