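"""Detector evaluation: leave-one-out accuracy and information transfer rate.

LOOCV follows the standard training-based SSVEP protocol: each recorded
trial takes a turn as the test signal while the remaining trials form the
training set, the model is refit per fold, and accuracy is the fraction of
correct decisions over all targets and folds.

The information transfer rate (ITR) of an N_f-choice synchronous interface
with accuracy P and command time T0 seconds is

    ITR = (1/T0) * [log2 N_f + P log2 P + (1-P) log2((1-P)/(N_f-1))]

in bits per second.  T0 is the full command period: flicker duration plus
the rest gap between consecutive trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import core, trca
from .data_model import TrainingSet

__all__ = ["EvalResult", "loocv_accuracy", "itr", "command_time", "round_half_up"]

_ALGORITHMS = {
    "itdma": (core.fit, core.classify),
    "trca": (trca.fit_trca, trca.classify_trca),
}


@dataclass
class EvalResult:
    """Outcome of an accuracy evaluation.

    ``confusion[i, j]`` counts trials of true target ``i+1`` classified as
    ``j+1``.  ``itr_bits_per_s`` is populated only when a command time was
    supplied.
    """

    accuracy: float
    n_correct: int
    n_total: int
    confusion: np.ndarray
    itr_bits_per_s: float | None = None
    t0_s: float | None = None


def loocv_accuracy(
    training: TrainingSet,
    algorithm: str = "itdma",
    t0_s: float | None = None,
) -> EvalResult:
    """Leave-one-out cross-validated accuracy of a detector.

    Every trial is held out once (N_f x N_t folds); the model is refit on
    the remaining trials each time.  Requires at least 3 trials per target
    so every fold retains the 2 trials the pairwise objective needs.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(_ALGORITHMS)}")
    fit_fn, classify_fn = _ALGORITHMS[algorithm]
    n_t = training.n_trials_per_target
    if n_t < 3:
        raise ValueError(
            f"LOOCV needs >= 3 trials per target (each fold must retain >= 2), got {n_t}"
        )
    n_f = training.n_targets
    confusion = np.zeros((n_f, n_f), dtype=int)
    for i in range(n_f):
        for m in range(n_t):
            fold_groups = [
                [t for k, t in enumerate(group) if not (gi == i and k == m)]
                for gi, group in enumerate(training.trials)
            ]
            fold = TrainingSet(trials=fold_groups, fs=training.fs)
            model = fit_fn(fold)
            pred = classify_fn(model, training.trials[i][m])
            confusion[i, pred - 1] += 1
    n_total = n_f * n_t
    n_correct = int(np.trace(confusion))
    accuracy = n_correct / n_total
    itr_val = None
    if t0_s is not None:
        itr_val = itr(max(accuracy, 1.0 / n_f), n_f, t0_s) if accuracy > 0 else 0.0
    return EvalResult(
        accuracy=accuracy,
        n_correct=n_correct,
        n_total=n_total,
        confusion=confusion,
        itr_bits_per_s=itr_val,
        t0_s=t0_s,
    )


def itr(p: float, nf: int, t0_s: float) -> float:
    """Information transfer rate in bits per second.

    ``p`` is the detection accuracy in (0, 1]; ``nf`` the number of targets
    (>= 2); ``t0_s`` the average time to output one command.  ``p = 1`` uses
    the 0*log2(0) := 0 convention, giving log2(nf)/t0; ``p = 1/nf`` gives 0.
    The formula attains its minimum (zero bits) exactly at chance accuracy;
    below-chance accuracies are flagged with a warning — the formula still
    yields a nonnegative number there, but it does not represent usable
    information — and the raw value is returned unclamped.
    """
    if not 0 < p <= 1:
        raise ValueError(f"accuracy must be in (0, 1], got {p}")
    if nf < 2:
        raise ValueError(f"need >= 2 targets, got {nf}")
    if t0_s <= 0:
        raise ValueError(f"command time must be positive, got {t0_s}")
    bits = math.log2(nf) + p * math.log2(p)
    if p < 1:
        bits += (1 - p) * math.log2((1 - p) / (nf - 1))
    rate = bits / t0_s
    if p * nf < 1 - 1e-12:
        warnings.warn(
            f"accuracy {p} is below chance 1/{nf}; the computed rate "
            f"({rate:.3g} bit/s) does not represent usable information",
            stacklevel=2,
        )
    return rate


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report display)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def command_time(flicker_s: float, rest_s: float) -> float:
    """Command period T0 = flicker duration + rest gap, seconds."""
    if flicker_s < 0 or rest_s < 0:
        raise ValueError("flicker and rest durations must be nonnegative")
    t0 = flicker_s + rest_s
    if t0 <= 0:
        raise ValueError("command time must be positive (flicker + rest > 0)")
    return t0
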