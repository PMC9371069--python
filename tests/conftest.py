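import numpy as np
import pytest

from itdma import MixingModel, StimulusConfig, generate_dataset
from itdma.sim import default_mixing


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_set():
    """High-determinism training set: evoked component only, no noise."""
    mix = MixingModel(r1=default_mixing().r1, r2=np.zeros(6))
    training, _ = generate_dataset(mix, n_t=5, duration_s=0.5, seed=1)
    return training


@pytest.fixture(scope="session")
def noisy_set():
    """Moderate-SNR training set with 6 trials per target."""
    training, _ = generate_dataset(
        default_mixing(snr_db=5.0), n_t=6, duration_s=1.0, seed=7
    )
    return training


def write_minimal_edf(path, data, fs, labels):
    """Emit a single-record EDF file (int16, one data record) for read tests.

    This is a synthetic stand-in for a recorded EDF: just enough of the
    format (fixed 256-byte header + per-signal headers + 2-byte samples) for
    readers to parse it.  Written at test run time only.
    """
    data = np.asarray(data, float)
    ns, n = data.shape
    dig_min, dig_max = -32768, 32767
    phys_min = np.floor(data.min(axis=1)) - 1
    phys_max = np.ceil(data.max(axis=1)) + 1

    def f(s, w):
        return str(s)[:w].ljust(w).encode("ascii")

    hdr = (
        f("0", 8) + f("X", 80) + f("X", 80) + f("01.01.20", 8) + f("00.00.00", 8)
        + f(256 * (1 + ns), 8) + f("", 44) + f(1, 8) + f(n / fs, 8) + f(ns, 4)
    )
    sig = b"".join(f(lab, 16) for lab in labels)
    sig += b"".join(f("", 80) for _ in labels)
    sig += b"".join(f("uV", 8) for _ in labels)
    sig += b"".join(f(v, 8) for v in phys_min)
    sig += b"".join(f(v, 8) for v in phys_max)
    sig += b"".join(f(dig_min, 8) for _ in labels)
    sig += b"".join(f(dig_max, 8) for _ in labels)
    sig += b"".join(f("", 80) for _ in labels)
    sig += b"".join(f(n, 8) for _ in labels)
    sig += b"".join(f("", 32) for _ in labels)
    body = b""
    for j in range(ns):
        scale = (dig_max - dig_min) / (phys_max[j] - phys_min[j])
        dig = np.round((data[j] - phys_min[j]) * scale + dig_min).astype("<i2")
        body += dig.tobytes()
    with open(path, "wb") as fh:
        fh.write(hdr + sig + body)
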