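"""Synthetic SSVEP dataset generator.

Emulates the linear observation model of multi-channel SSVEP recordings:
channel j observes

    x_j(t) = r1[j] * s(t) + r2[j] * n_j(t),

a shared task-related periodic component s(t) (the evoked response: a
harmonic stack phase-locked to the flicker) mixed with channel-specific
background noise n_j(t).  Defaults mirror a driving-mode selection
interface: 3 targets flickering at 10/12/14 Hz, 6 occipital channels at a
250 Hz processing rate, with a signal-gain gradient peaking at Oz-like
channels to emulate occipital topography.

Background noise is pink (1/f) by default, generated by FFT spectral
shaping, independent across channels, and fully seedable.  Trial amplitude
is rescaled so the realized narrowband SNR — signal power over noise power
within +/-1 Hz of the fundamental, averaged over channels — matches a
requested dB level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .data_model import EEGTrial, StimulusConfig, TrainingSet

__all__ = [
    "MixingModel",
    "default_mixing",
    "generate_ssvep_component",
    "generate_noise",
    "generate_trial",
    "generate_dataset",
    "OCCIPITAL_CHANNELS",
]

OCCIPITAL_CHANNELS = ["POz", "PO4", "PO6", "O1", "Oz", "O2"]

# signal-gain gradient: strongest at Oz, weaker at parieto-occipital sites
_DEFAULT_R1_6CH = np.array([0.60, 0.65, 0.70, 0.85, 1.00, 0.90])


@dataclass
class MixingModel:
    """Forward model: per-channel gains, harmonic content, noise spectrum.

    ``snr_db`` is the target narrowband SNR (dB) realized per trial; set
    ``r1`` to zeros for pure noise or ``r2`` to zeros for noiseless trials
    (in either degenerate case no SNR rescaling is applied).
    """

    r1: np.ndarray
    r2: np.ndarray
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    noise_exponent: float = 1.0
    snr_db: float = 0.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, float)
        self.r2 = np.asarray(self.r2, float)
        if self.r1.shape != self.r2.shape or self.r1.ndim != 1:
            raise ValueError("r1 and r2 must be 1-D and the same length")
        if not (np.all(np.isfinite(self.r1)) and np.all(np.isfinite(self.r2))):
            raise ValueError("mixing gains must be finite")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.channel_names is None:
            n = len(self.r1)
            self.channel_names = (
                list(OCCIPITAL_CHANNELS) if n == 6 else [f"ch{j + 1}" for j in range(n)]
            )

    @property
    def n_channels(self) -> int:
        return len(self.r1)


def default_mixing(n_channels: int = 6, snr_db: float = 0.0, **kwargs) -> MixingModel:
    """Occipital-gradient mixing model; 6 channels reproduce the PO/O montage."""
    if n_channels == 6:
        r1 = _DEFAULT_R1_6CH.copy()
    else:
        r1 = np.linspace(0.5, 1.0, n_channels)
    return MixingModel(r1=r1, r2=np.ones(n_channels), snr_db=snr_db, **kwargs)


def generate_ssvep_component(
    freq_hz: float,
    phase_rad: float,
    duration_s: float,
    fs: float,
    n_harmonics: int = 3,
    harmonic_decay: float = 0.5,
) -> np.ndarray:
    """Harmonic stack: sum_k decay^(k-1) sin(2 pi k f t + k phase).

    Harmonic k rides at k times the fundamental frequency and phase
    (phase-locked flicker model).  Every harmonic must stay below Nyquist.
    """
    if freq_hz * n_harmonics >= fs / 2:
        raise ValueError(
            f"harmonic {n_harmonics} of {freq_hz} Hz reaches "
            f"{freq_hz * n_harmonics} Hz, above Nyquist {fs / 2} Hz"
        )
    n = int(np.floor(duration_s * fs + 0.5))
    t = np.arange(n) / fs
    out = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        out += harmonic_decay ** (k - 1) * np.sin(
            2 * np.pi * k * freq_hz * t + k * phase_rad
        )
    return out


def generate_noise(
    duration_s: float,
    fs: float,
    exponent: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean 1/f^alpha noise via FFT spectral shaping, unit variance.

    ``exponent`` 0 gives white noise; 1 gives the pink spectrum typical of
    EEG background.  Reproducible for a given seed or Generator.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * fs + 0.5))
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


BAND_HALF_WIDTH_HZ = 1.0


def _expected_band_noise_power(n: int, fs: float, exponent: float, f0: float) -> float:
    """Expected noise power within +/-1 Hz of f0 for unit-variance 1/f^a noise.

    Derived from the spectral-shaping construction itself: the expected PSD
    is proportional to f^-a over the resolvable bins, normalized to unit
    total variance.  Using the expected (not realized) density makes the SNR
    calibration deterministic — every trial of a given length gets the same
    signal amplitude, and the realized narrowband SNR matches the target in
    expectation over noise draws.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]
    density = f0 ** (-exponent) / (np.sum(freqs ** (-exponent)) * (fs / n))
    return 2.0 * BAND_HALF_WIDTH_HZ * density


def generate_trial(
    mixing: MixingModel,
    stimulus: StimulusConfig,
    target_index: int,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> EEGTrial:
    """One labeled epoch: per-channel signal/noise mixture at the target SNR.

    The signal component is globally rescaled (channel ratios preserved) so
    that the realized narrowband SNR at the fundamental matches
    ``mixing.snr_db``; degenerate cases (no signal or no noise) skip the
    rescaling.
    """
    if not 1 <= target_index <= stimulus.n_targets:
        raise ValueError(
            f"target_index {target_index} outside 1..{stimulus.n_targets}"
        )
    rng = np.random.default_rng(seed)
    f0 = stimulus.frequencies_hz[target_index - 1]
    s = generate_ssvep_component(
        f0,
        stimulus.phases_rad[target_index - 1],
        duration_s,
        fs,
        mixing.n_harmonics,
        mixing.harmonic_decay,
    )
    n = len(s)
    noise = np.vstack(
        [mixing.r2[j] * generate_noise(duration_s, fs, mixing.noise_exponent, rng)
         for j in range(mixing.n_channels)]
    )
    sig = np.outer(mixing.r1, s)
    has_signal = np.any(mixing.r1 != 0) and sig.any()
    noisy = [j for j in range(mixing.n_channels) if np.any(noise[j])]
    if has_signal and noisy:
        pn_unit = _expected_band_noise_power(n, fs, mixing.noise_exponent, f0)
        snrs = []
        for j in noisy:
            # fundamental power is analytic: amplitude r1[j], sine power /2
            ps = 0.5 * mixing.r1[j] ** 2
            pn = mixing.r2[j] ** 2 * pn_unit
            if pn > 0:
                snrs.append(ps / pn)
        current = float(np.mean(snrs))
        target = 10.0 ** (mixing.snr_db / 10.0)
        sig = sig * np.sqrt(target / current)
    data = sig + noise
    return EEGTrial(
        data=data,
        fs=fs,
        channel_names=list(mixing.channel_names),
        target_index=target_index,
    )


def generate_dataset(
    mixing: MixingModel,
    stimulus: StimulusConfig | None = None,
    n_t: int = 10,
    trials_per_target_test: int = 0,
    duration_s: float = 1.0,
    fs: float = 250.0,
    seed: int | None = None,
) -> tuple[TrainingSet, list[EEGTrial]]:
    """Balanced training set plus labeled test trials.

    Noise realizations are drawn from independent seed-sequence children, so
    train and test trials never share noise; the deterministic evoked
    component is identical across seeds.  Test trials follow a predetermined
    target-major order (target 1 trials, then target 2, ...).
    """
    if stimulus is None:
        stimulus = StimulusConfig()
    if n_t < 2:
        raise ValueError("n_t must be >= 2")
    ss = np.random.SeedSequence(seed)
    n_train = stimulus.n_targets * n_t
    n_test = stimulus.n_targets * trials_per_target_test
    children = ss.spawn(n_train + n_test)
    k = 0
    groups: list[list[EEGTrial]] = []
    for i in range(1, stimulus.n_targets + 1):
        group = []
        for _ in range(n_t):
            group.append(
                generate_trial(
                    mixing, stimulus, i, duration_s, fs,
                    seed=np.random.default_rng(children[k]),
                )
            )
            k += 1
        groups.append(group)
    test: list[EEGTrial] = []
    for i in range(1, stimulus.n_targets + 1):
        for _ in range(trials_per_target_test):
            test.append(
                generate_trial(
                    mixing, stimulus, i, duration_s, fs,
                    seed=np.random.default_rng(children[k]),
                )
            )
            k += 1
    return TrainingSet(trials=groups, fs=fs), test
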