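import numpy as np
import pytest

from mngsort.preprocessing import AlignedWaveform, differentiate
from mngsort.synthetic import SyntheticConfig, generate_recording


def make_waveform(samples, track="Track1", fd=None, sd=None):
    """AlignedWaveform from raw samples (derivatives computed unless given)."""
    samples = np.asarray(samples, dtype=np.float64)
    if fd is None or sd is None:
        fd, sd = differentiate(samples)
    return AlignedWaveform(
        samples=samples, fd=np.asarray(fd, dtype=np.float64),
        sd=np.asarray(sd, dtype=np.float64),
        align_index=int(np.argmin(fd)), source_time=0.0, track=track,
    )


def gaussian_pulse(sigma, center=30.0, n=60, amp=1.0):
    i = np.arange(n)
    return amp * np.exp(-((i - center) ** 2) / (2 * sigma**2))


@pytest.fixture(scope="session")
def two_fiber_recording():
    """A small default-condition marking-method recording (10 kHz, 2 fibers)."""
    return generate_recording(SyntheticConfig(n_sweeps=25, seed=7))


@pytest.fixture(scope="session")
def two_fiber_waveforms(two_fiber_recording):
    from mngsort.preprocessing import extract_aligned_waveforms

    waveforms, exclusions = extract_aligned_waveforms(two_fiber_recording)
    assert not exclusions
    return waveforms
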