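import numpy as np
import pytest

from eegsen import EEGRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def white_record(rng):
    """A 34-minute single-channel white-noise record at 256 Hz, onset at end.

    Long enough for the default 32-minute display segment.
    """
    n = 34 * 60 * 256
    return EEGRecord(
        samples=rng.standard_normal(n)[np.newaxis, :],
        sampling_rate_hz=256.0,
        seizure_onset_s=34 * 60.0,
        channel_labels=["focal"],
        record_id="white-34min",
    )


def brute_force_sen(powers, log=np.log):
    """Independent recomputation of normalized spectral entropy.

    Plain summation over the given bin powers with an arbitrary log base;
    used as the oracle against the library implementation.
    """
    powers = [float(p) for p in powers]
    total = sum(powers)
    if total <= 0:
        return float("nan")
    acc = 0.0
    for p in powers:
        q = p / total
        if q > 0:
            acc -= q * float(log(q))
    return acc / float(log(len(powers)))
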