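import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from batrack import build_default_array


@pytest.fixture(scope="session")
def array():
    return build_default_array()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_chirp_recording(array, shifts_samples, fs=300_000.0, snr_db=None, seed=0):
    """8-channel recording: a 5 ms FM sweep on the reference channel and the
    same sweep shifted by ``shifts_samples[k]`` (possibly fractional) on each
    non-reference channel; optional Gaussian noise at ``snr_db``."""
    from batrack.simulate import _fm_downsweep

    dur = 0.06
    n = int(dur * fs)
    t_call = 0.025
    samples = np.zeros((8, n))
    tt = np.arange(n) / fs
    ref_sig = _fm_downsweep(tt - t_call, 100e3, 45e3, 0.005)
    samples[array.reference_index] = ref_sig
    for k, ch in enumerate(array.non_reference_indices):
        delay = shifts_samples[k] / fs
        samples[ch] = _fm_downsweep(tt - t_call - delay, 100e3, 45e3, 0.005)
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        call_rms = np.sqrt(np.mean(ref_sig[ref_sig != 0] ** 2))
        samples += rng.normal(0, call_rms * 10 ** (-snr_db / 20), samples.shape)
    from batrack import MultiChannelRecording

    return MultiChannelRecording(sample_rate=fs, samples=samples)
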