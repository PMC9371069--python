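"""Core domain types and file I/O for multi-channel EEG epochs.

An epoch ("trial") is a channels x samples real matrix in microvolts with a
sampling rate and ordered channel labels.  Trials are grouped per stimulation
target into a :class:`TrainingSet`.  Two on-disk representations are
supported:

* EDF recordings (read-only, via :mod:`mne`), and
* a plain-text fixture dialect: one tab-separated matrix per trial
  (rows = channels, full decimal precision) plus a single JSON manifest per
  dataset carrying the sampling rate, channel names and target labels.

The delimited dialect round-trips bit-exactly and diffs cleanly, which makes
it suitable for test fixtures and cross-language exchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEGTrial",
    "TrainingSet",
    "StimulusConfig",
    "ValidationError",
    "ParseError",
    "read_trials",
    "write_trials",
]

MANIFEST_NAME = "manifest.json"


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class ParseError(ValueError):
    """A file could not be interpreted in the declared format."""


@dataclass
class EEGTrial:
    """One EEG epoch: a channels x samples matrix plus metadata.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    channel_names
        Ordered channel labels, one per row of ``data``.  Labels are opaque
        strings; no montage validation is attempted.
    target_index
        Optional 1-based index of the stimulation target that elicited the
        epoch.
    onset_s
        Optional stimulus-onset time within the source recording, seconds.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    target_index: int | None = None
    onset_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise ValidationError(
                f"trial data must be 2-D (channels x samples), got shape {self.data.shape}"
            )
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but {len(self.channel_names)} "
                "channel names were declared"
            )
        if self.data.shape[1] < 2:
            raise ValidationError(
                f"trial must have at least 2 samples, got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("trial data contains NaN or Inf entries")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.target_index is not None and int(self.target_index) < 1:
            raise ValidationError(
                f"target_index is 1-based and must be >= 1, got {self.target_index}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "EEGTrial":
        """New trial with replaced data (and optionally fs), same metadata."""
        return EEGTrial(
            data=np.asarray(data, dtype=float),
            fs=self.fs if fs is None else fs,
            channel_names=list(self.channel_names),
            target_index=self.target_index,
            onset_s=self.onset_s,
        )


@dataclass
class TrainingSet:
    """Per-target collections of training trials.

    ``trials[i]`` holds the ordered trials recorded for target ``i + 1``
    (targets are 1-based throughout).  All trials must share channel count,
    channel order, sample count and sampling rate; every target needs at
    least two trials because the inter-trial objective is built from pairwise
    trial differences.
    """

    trials: list[list[EEGTrial]]
    fs: float

    def __post_init__(self) -> None:
        if len(self.trials) < 2:
            raise ValidationError(
                f"a training set needs >= 2 targets, got {len(self.trials)}"
            )
        ref: EEGTrial | None = None
        for i, group in enumerate(self.trials, start=1):
            if len(group) < 2:
                raise ValidationError(
                    f"target {i} has {len(group)} trials; >= 2 are required "
                    "(pairwise trial differences need at least two trials)"
                )
            for trial in group:
                if ref is None:
                    ref = trial
                    if not np.isclose(ref.fs, self.fs):
                        raise ValidationError(
                            f"training-set fs {self.fs} != trial fs {ref.fs}"
                        )
                    continue
                if trial.data.shape != ref.data.shape:
                    raise ValidationError(
                        f"trial shape {trial.data.shape} != expected {ref.data.shape} "
                        f"(target {i})"
                    )
                if not np.isclose(trial.fs, ref.fs):
                    raise ValidationError(
                        f"trial fs {trial.fs} != expected {ref.fs} (target {i})"
                    )
                if list(trial.channel_names) != list(ref.channel_names):
                    raise ValidationError(
                        f"channel order mismatch in target {i}: "
                        f"{trial.channel_names} != {ref.channel_names}"
                    )

    @property
    def n_targets(self) -> int:
        return len(self.trials)

    @property
    def n_trials_per_target(self) -> int:
        return len(self.trials[0])

    @property
    def n_channels(self) -> int:
        return self.trials[0][0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0][0].n_samples

    @property
    def channel_names(self) -> list[str]:
        return list(self.trials[0][0].channel_names)

    def matrices(self, target_index: int) -> list[np.ndarray]:
        """Data matrices for 1-based target ``target_index``."""
        return [t.data for t in self.trials[target_index - 1]]

    def flat_trials(self) -> list[EEGTrial]:
        return [t for group in self.trials for t in group]


@dataclass
class StimulusConfig:
    """Timing and frequency layout of the flickering stimuli.

    The interface cycles with period ``cycle_s``: a flicker stage during
    which all targets blink at their assigned frequencies, followed by a rest
    stage.  ``latency_s`` is the visual-pathway latency: the evoked response
    lags the stimulus onset, so analysis windows start that much later.
    """

    frequencies_hz: Sequence[float] = (10.0, 12.0, 14.0)
    phases_rad: Sequence[float] | None = None
    flicker_s: float = 1.5
    rest_s: float = 3.5
    latency_s: float = 0.135

    def __post_init__(self) -> None:
        self.frequencies_hz = [float(f) for f in self.frequencies_hz]
        if self.phases_rad is None:
            self.phases_rad = [0.0] * len(self.frequencies_hz)
        self.phases_rad = [float(p) for p in self.phases_rad]
        if len(self.phases_rad) != len(self.frequencies_hz):
            raise ValidationError(
                f"{len(self.frequencies_hz)} frequencies but "
                f"{len(self.phases_rad)} phases"
            )
        if any(f <= 0 for f in self.frequencies_hz):
            raise ValidationError("stimulus frequencies must be strictly positive")
        if len(set(self.frequencies_hz)) != len(self.frequencies_hz):
            raise ValidationError("stimulus frequencies must be pairwise distinct")
        if self.flicker_s < 0 or self.rest_s < 0:
            raise ValidationError("flicker_s and rest_s must be nonnegative")
        if self.latency_s < 0:
            raise ValidationError("latency_s must be nonnegative")

    @property
    def n_targets(self) -> int:
        return len(self.frequencies_hz)

    @property
    def cycle_s(self) -> float:
        return self.flicker_s + self.rest_s


# ---------------------------------------------------------------------------
# delimited + manifest dialect
# ---------------------------------------------------------------------------

def _write_matrix(path: Path, data: np.ndarray) -> None:
    np.savetxt(path, data, fmt="%.17g", delimiter="\t")


def _read_matrix(path: Path) -> np.ndarray:
    try:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return mat


def write_trials(
    trials: TrainingSet | Sequence[EEGTrial],
    path: str | Path,
    format: str = "delimited",
) -> None:
    """Write trials to ``path`` (a directory) in the delimited dialect.

    A :class:`TrainingSet` is flattened target-major; the manifest records
    each trial's target so :func:`read_trials` can rebuild the grouping.
    """
    if format != "delimited":
        raise ValueError(f"unsupported write format: {format!r} (only 'delimited')")
    if isinstance(trials, TrainingSet):
        kind = "training_set"
        flat = trials.flat_trials()
        fs = trials.fs
    else:
        kind = "trial_list"
        flat = list(trials)
        if not flat:
            raise ValidationError("refusing to write an empty trial list")
        fs = flat[0].fs
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, trial in enumerate(flat):
        fname = f"trial_{k:04d}.tsv"
        _write_matrix(path / fname, trial.data)
        entries.append(
            {
                "file": fname,
                "target_index": trial.target_index,
                "onset_s": trial.onset_s,
            }
        )
    manifest = {
        "kind": kind,
        "fs": fs,
        "channel_names": list(flat[0].channel_names),
        "trials": entries,
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))


def _read_delimited(path: Path) -> TrainingSet | list[EEGTrial]:
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise ParseError(f"no {MANIFEST_NAME} in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{manifest_path}: invalid JSON ({exc})") from exc
    for key in ("kind", "fs", "channel_names", "trials"):
        if key not in manifest:
            raise ParseError(f"{manifest_path}: missing required field {key!r}")
    fs = float(manifest["fs"])
    names = list(manifest["channel_names"])
    trials: list[EEGTrial] = []
    for entry in manifest["trials"]:
        mat = _read_matrix(path / entry["file"])
        if mat.shape[0] != len(names):
            raise ValidationError(
                f"{entry['file']}: {mat.shape[0]} rows but {len(names)} "
                "channels declared in manifest"
            )
        trials.append(
            EEGTrial(
                data=mat,
                fs=fs,
                channel_names=names,
                target_index=entry.get("target_index"),
                onset_s=entry.get("onset_s"),
            )
        )
    if manifest["kind"] == "training_set":
        groups: dict[int, list[EEGTrial]] = {}
        for t in trials:
            if t.target_index is None:
                raise ValidationError(
                    "training-set manifest contains a trial without target_index"
                )
            groups.setdefault(t.target_index, []).append(t)
        ordered = [groups[i] for i in sorted(groups)]
        return TrainingSet(trials=ordered, fs=fs)
    return trials


def _read_edf(path: Path) -> list[EEGTrial]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne loads EDF in volts; epochs elsewhere in this package are in uV
    data = raw.get_data() * 1e6
    return [
        EEGTrial(
            data=data,
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
        )
    ]


def read_trials(
    path: str | Path, format: str = "auto"
) -> TrainingSet | list[EEGTrial]:
    """Read trials from ``path``.

    ``format`` may be ``"edf"``, ``"delimited"``, or ``"auto"`` (EDF when the
    suffix is ``.edf``, delimited when ``path`` is a directory holding a
    manifest).  EDF recordings come back as a single whole-recording trial;
    epoching is left to :mod:`itdma.preprocess`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {format!r}")
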