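"""Inter-trial distance minimization analysis (ITDMA) for SSVEP detection.

The detector learns, for each stimulation target, a spatial filter w (one
weight per EEG channel) that makes same-target training trials look as alike
as possible after spatial combination: it minimizes the summed squared
Euclidean distances between all ordered pairs of filtered training trials,

    sum_{m1 != m2} || w' G_m1 - w' G_m2 ||_2^2  =  w' P w,

subject to the combined training signal having unit power, w' Q w = 1, where

    P = sum_{m1 != m2} (G_m1 - G_m2)(G_m1 - G_m2)',
    Q[j1, j2] = sum_m Cov(G_m[j1, :], G_m[j2, :]).

The constrained minimum is the generalized eigenvector of (P, Q) with the
smallest eigenvalue.  At test time the per-target filters are stacked into
an ensemble matrix E and a test epoch S is assigned to the target whose
spatially filtered template (the per-target trial average) is nearest in
Frobenius norm:

    pick argmin_i || E'S - E' Tbar_i ||_F.

Distances, not correlations, are the decision metric — this is what sets the
method apart from TRCA-style detectors (see :mod:`itdma.trca`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg

from .data_model import EEGTrial, TrainingSet, _read_matrix, _write_matrix
import json

__all__ = [
    "SpatialFilter",
    "ItdmaModel",
    "compute_scatter_P",
    "compute_power_Q",
    "solve_spatial_filter",
    "fit",
    "decision_distances",
    "classify",
    "save_model",
    "load_model",
]

RIDGE_SCALE = 1e-8


@dataclass
class SpatialFilter:
    """One per-target channel-weight vector.

    ``w`` satisfies the unit-power constraint ``w' Q w = 1`` and is
    sign-canonicalized: the entry of largest magnitude is positive.  The
    decision rule is sign-sensitive through the ensemble matrix, so the
    convention is fixed rather than left to the eigensolver.
    """

    w: np.ndarray
    target_index: int
    objective_value: float


@dataclass
class ItdmaModel:
    """Trained detector: ensemble filter + per-target templates.

    ``ensemble`` has shape ``(n_channels, n_targets)``; column ``i`` is the
    spatial filter trained on target ``i + 1``'s trials.  ``templates[i]``
    is the plain arithmetic mean of that target's training trials.
    """

    ensemble: np.ndarray
    templates: list[np.ndarray]
    fs: float
    filters: list[SpatialFilter] | None = None
    channel_names: list[str] | None = None

    @property
    def n_targets(self) -> int:
        return self.ensemble.shape[1]

    @property
    def n_channels(self) -> int:
        return self.ensemble.shape[0]

    @property
    def template_length(self) -> int:
        return self.templates[0].shape[1]


def _as_matrices(trials: Sequence[np.ndarray | EEGTrial]) -> list[np.ndarray]:
    mats = [t.data if isinstance(t, EEGTrial) else np.asarray(t, float) for t in trials]
    shape = mats[0].shape
    for m in mats:
        if m.ndim != 2 or m.shape != shape:
            raise ValueError(
                f"all trials must share shape {shape}, got {m.shape}"
            )
    return mats


def _center(mats: list[np.ndarray]) -> list[np.ndarray]:
    return [m - m.mean(axis=1, keepdims=True) for m in mats]


def compute_scatter_P(
    trials: Sequence[np.ndarray | EEGTrial], center: bool = True
) -> np.ndarray:
    """Inter-trial scatter matrix P over all ordered pairs of trials.

    Computed via the closed form
    ``2 * N_t * sum_m G_m G_m' - 2 * (sum_m G_m)(sum_m G_m)'``
    which is algebraically identical to the ordered-pair double sum.
    Per-channel means are removed from each trial first (default; band-passed
    EEG is near zero-mean anyway, and centering keeps P consistent with the
    covariance-based Q).
    """
    mats = _as_matrices(trials)
    if len(mats) < 2:
        raise ValueError(f"need >= 2 trials for pairwise scatter, got {len(mats)}")
    if center:
        mats = _center(mats)
    n_t = len(mats)
    total = np.zeros((mats[0].shape[0],) * 2)
    s = np.zeros_like(mats[0])
    for m in mats:
        total += m @ m.T
        s += m
    P = 2.0 * n_t * total - 2.0 * (s @ s.T)
    return 0.5 * (P + P.T)


def compute_power_Q(
    trials: Sequence[np.ndarray | EEGTrial], center: bool = True
) -> np.ndarray:
    """Aggregate power matrix Q: sum over trials of channel covariances.

    Covariance uses the unbiased (T - 1) divisor.  ``center`` is accepted for
    symmetry with :func:`compute_scatter_P` but covariance centers
    internally, so it does not change the result.
    """
    mats = _as_matrices(trials)
    T = mats[0].shape[1]
    if T < 2:
        raise ValueError(f"covariance needs >= 2 samples per trial, got {T}")
    Q = np.zeros((mats[0].shape[0],) * 2)
    for m in mats:
        c = m - m.mean(axis=1, keepdims=True)
        Q += (c @ c.T) / (T - 1)
    return 0.5 * (Q + Q.T)


def solve_spatial_filter(
    P: np.ndarray, Q: np.ndarray, target_index: int = 1
) -> SpatialFilter:
    """Minimize ``w' P w`` subject to ``w' Q w = 1``.

    Solved as a symmetric-definite generalized eigenproblem; the minimizer
    is the eigenvector of the smallest eigenvalue.  Q is regularized with a
    relative ridge ``1e-8 * trace(Q)/N_c`` before factorization to guard
    against rank deficiency with few channels or samples.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"P and Q must be square and conformable, got {P.shape}, {Q.shape}")
    n = P.shape[0]
    tr = np.trace(Q)
    if tr <= 0:
        raise np.linalg.LinAlgError(
            "Q has nonpositive trace: the training trials carry no power; "
            "provide more data or nonconstant channels"
        )
    Qr = Q + (RIDGE_SCALE * tr / n) * np.eye(n)
    try:
        vals, vecs = linalg.eigh(P, Qr)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "generalized eigenproblem failed: Q is singular beyond ridge "
            "repair; provide more trials/samples or drop degenerate channels"
        ) from exc
    w = vecs[:, 0]  # eigenvalues ascending; ties broken by taking the first
    # enforce the unit-power constraint exactly against the ridged Q
    w = w / np.sqrt(w @ Qr @ w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return SpatialFilter(
        w=w, target_index=target_index, objective_value=float(w @ P @ w)
    )


def fit(training: TrainingSet, center: bool = True) -> ItdmaModel:
    """Training stage: one spatial filter per target, plus averaged templates.

    Filters are estimated target-independently (target i's filter uses only
    target i's trials); templates are the raw per-target trial means.
    """
    filters = []
    templates = []
    cols = []
    for i in range(1, training.n_targets + 1):
        mats = training.matrices(i)
        P = compute_scatter_P(mats, center=center)
        Q = compute_power_Q(mats, center=center)
        f = solve_spatial_filter(P, Q, target_index=i)
        filters.append(f)
        cols.append(f.w)
        templates.append(np.mean(mats, axis=0))
    return ItdmaModel(
        ensemble=np.column_stack(cols),
        templates=templates,
        fs=training.fs,
        filters=filters,
        channel_names=training.channel_names,
    )


def _test_matrix(model: ItdmaModel, S: EEGTrial | np.ndarray) -> np.ndarray:
    mat = S.data if isinstance(S, EEGTrial) else np.asarray(S, float)
    if mat.shape != (model.n_channels, model.template_length):
        raise ValueError(
            f"test signal shape {mat.shape} does not match model "
            f"({model.n_channels} channels x {model.template_length} samples); "
            "no implicit truncation or padding is performed"
        )
    return mat


def decision_distances(model: ItdmaModel, S: EEGTrial | np.ndarray) -> np.ndarray:
    """Frobenius distances ``||E'S - E'Tbar_i||_F`` for every target i."""
    mat = _test_matrix(model, S)
    Et = model.ensemble.T
    proj = Et @ mat
    return np.array(
        [np.linalg.norm(proj - Et @ tmpl, ord="fro") for tmpl in model.templates]
    )


def classify(model: ItdmaModel, S: EEGTrial | np.ndarray) -> int:
    """Detected target (1-based): argmin of the template distances.

    Exact ties resolve to the lowest index (np.argmin convention).
    """
    return int(np.argmin(decision_distances(model, S))) + 1


# ---------------------------------------------------------------------------
# model serialization (same delimited dialect as data_model)
# ---------------------------------------------------------------------------

def save_model(model: ItdmaModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_matrix(path / "ensemble.tsv", model.ensemble)
    for i, tmpl in enumerate(model.templates, start=1):
        _write_matrix(path / f"template_{i:02d}.tsv", tmpl)
    manifest = {
        "kind": "itdma_model",
        "fs": model.fs,
        "n_targets": model.n_targets,
        "channel_names": model.channel_names,
    }
    (path / "model.json").write_text(json.dumps(manifest, indent=1))


def load_model(path: str | Path) -> ItdmaModel:
    path = Path(path)
    manifest = json.loads((path / "model.json").read_text())
    ensemble = _read_matrix(path / "ensemble.tsv")
    templates = [
        _read_matrix(path / f"template_{i:02d}.tsv")
        for i in range(1, manifest["n_targets"] + 1)
    ]
    return ItdmaModel(
        ensemble=ensemble,
        templates=templates,
        fs=float(manifest["fs"]),
        channel_names=manifest.get("channel_names"),
    )
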