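"""Fixed EEG preprocessing chain for SSVEP epochs.

Raw recordings (typically 1000 Hz) are down-sampled to a 250 Hz processing
rate, power-line interference is removed with a 50 Hz notch, the band of
interest is isolated with a 7-70 Hz band-pass, and the analysis window is
cropped starting 135 ms after stimulus onset to account for visual-pathway
latency.  All filters are applied forward-backward (zero phase) so that
template matching downstream is not biased by group delay.

Filter choices: 4th-order Butterworth band-pass and a second-order IIR notch
with quality factor 30.  Resampling is polyphase (anti-alias FIR + rational
rate change); for the 1000 -> 250 Hz case this reduces to filtered integer
decimation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .data_model import EEGTrial, StimulusConfig

__all__ = [
    "resample",
    "notch_filter",
    "bandpass_filter",
    "crop_epoch",
    "preprocess_pipeline",
    "DEFAULT_TARGET_FS",
    "DEFAULT_NOTCH_HZ",
    "DEFAULT_BAND_HZ",
    "DEFAULT_LATENCY_S",
]

DEFAULT_TARGET_FS = 250.0
DEFAULT_NOTCH_HZ = 50.0
DEFAULT_BAND_HZ = (7.0, 70.0)
DEFAULT_LATENCY_S = 0.135

NOTCH_Q = 30.0
BUTTER_ORDER = 4


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def resample(trial: EEGTrial, target_fs: float) -> EEGTrial:
    """Down-sample a trial to ``target_fs`` with anti-alias filtering.

    Only down-sampling is supported.  The rate change is performed with a
    polyphase FIR resampler; duration is preserved to within one output
    sample.
    """
    if target_fs > trial.fs:
        raise ValueError(
            f"target_fs {target_fs} exceeds trial fs {trial.fs}; upsampling "
            "is not supported"
        )
    if np.isclose(target_fs, trial.fs):
        return trial.copy_with(trial.data.copy())
    frac = Fraction(target_fs / trial.fs).limit_denominator(1000)
    out = signal.resample_poly(trial.data, frac.numerator, frac.denominator, axis=1)
    return trial.copy_with(out, fs=target_fs)


def notch_filter(trial: EEGTrial, center_hz: float = DEFAULT_NOTCH_HZ) -> EEGTrial:
    """Zero-phase second-order notch at ``center_hz`` (power-line removal)."""
    if not 0 < center_hz < trial.fs / 2:
        raise ValueError(
            f"notch center {center_hz} Hz must lie in (0, Nyquist={trial.fs / 2})"
        )
    b, a = signal.iirnotch(center_hz, NOTCH_Q, fs=trial.fs)
    out = signal.filtfilt(b, a, trial.data, axis=1)
    return trial.copy_with(out)


def bandpass_filter(
    trial: EEGTrial,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> EEGTrial:
    """Zero-phase Butterworth band-pass between ``low_hz`` and ``high_hz``."""
    nyq = trial.fs / 2
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist; got "
            f"({low_hz}, {high_hz}) with Nyquist {nyq}"
        )
    sos = signal.butter(
        BUTTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=trial.fs, output="sos"
    )
    out = signal.sosfiltfilt(sos, trial.data, axis=1)
    return trial.copy_with(out)


def crop_epoch(
    trial: EEGTrial,
    onset_s: float,
    latency_s: float,
    duration_s: float,
) -> EEGTrial:
    """Extract the analysis window ``[onset + latency, onset + latency + duration)``.

    Sample indices are rounded half-up: at 250 Hz a 135 ms latency lands on
    sample 34 (0.135 x 250 = 33.75).  The window is half-open, 0-based.
    """
    start = _round_half_up((onset_s + latency_s) * trial.fs)
    length = _round_half_up(duration_s * trial.fs)
    if start < 0 or length < 1:
        raise ValueError(f"empty or negative window: start={start}, length={length}")
    end = start + length
    if end > trial.n_samples:
        raise ValueError(
            f"crop window needs samples [{start}, {end}) but trial has only "
            f"{trial.n_samples} samples"
        )
    out = trial.copy_with(trial.data[:, start:end])
    out.onset_s = None
    return out


def preprocess_pipeline(
    trial: EEGTrial,
    config: StimulusConfig | None = None,
    duration_s: float | None = None,
    target_fs: float = DEFAULT_TARGET_FS,
    notch_hz: float = DEFAULT_NOTCH_HZ,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    onset_s: float | None = None,
) -> EEGTrial:
    """Full chain: resample, notch + band-pass, latency crop.

    ``onset_s`` defaults to the trial's recorded onset (or 0); ``duration_s``
    defaults to whatever remains after the latency.  The latency is taken
    from ``config`` (135 ms by default).
    """
    if config is None:
        config = StimulusConfig()
    out = resample(trial, target_fs)
    out = notch_filter(out, notch_hz)
    out = bandpass_filter(out, band_hz[0], band_hz[1])
    if onset_s is None:
        onset_s = trial.onset_s or 0.0
    if duration_s is None:
        duration_s = out.duration_s - onset_s - config.latency_s
    return crop_epoch(out, onset_s, config.latency_s, duration_s)
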