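"""Task-related component analysis (TRCA) baseline detector.

TRCA is the standard training-based SSVEP detector used for head-to-head
comparisons.  Per target, it finds the channel-weight vector that maximizes
inter-trial covariance of the filtered signal relative to its aggregate
variance — the mirror image of the distance-minimizing objective in
:mod:`itdma.core` (maximal instead of minimal generalized eigenvector, and a
correlation rather than a distance decision rule).

The ensemble variant is implemented: all per-target filters are stacked and
the test epoch is assigned to the target whose filtered template correlates
best with the filtered test signal.  Internals follow the TRCA literature,
not anything specific to this package's distance-based detector.
"""

from __future__ import annotations

import numpy as np

from .core import ItdmaModel, SpatialFilter, _center, _as_matrices, _test_matrix
from .data_model import TrainingSet
from scipy import linalg

__all__ = ["fit_trca", "classify_trca", "trca_correlations"]

RIDGE_SCALE = 1e-8


def _trca_filter(mats: list[np.ndarray], target_index: int) -> SpatialFilter:
    """Maximal generalized eigenvector of (S, Q) for one target's trials.

    S aggregates cross-trial covariances, Q the within-trial covariances of
    the concatenated data; both built from per-channel-centered trials.
    """
    mats = _center(mats)
    n_c = mats[0].shape[0]
    total = sum(m @ m.T for m in mats)
    u = sum(mats)
    S = u @ u.T - total  # sum over ordered pairs m1 != m2 of G_m1 G_m2'
    Q = total
    Qr = Q + (RIDGE_SCALE * np.trace(Q) / n_c) * np.eye(n_c)
    vals, vecs = linalg.eigh(0.5 * (S + S.T), Qr)
    w = vecs[:, -1]  # maximal eigenvalue
    w = w / np.sqrt(w @ Qr @ w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return SpatialFilter(w=w, target_index=target_index, objective_value=float(vals[-1]))


def fit_trca(training: TrainingSet) -> ItdmaModel:
    """Train ensemble TRCA; returns the same model shape as the ITDMA fit."""
    filters, cols, templates = [], [], []
    for i in range(1, training.n_targets + 1):
        mats = _as_matrices(training.matrices(i))
        f = _trca_filter(mats, i)
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


def trca_correlations(model: ItdmaModel, S) -> np.ndarray:
    """Pearson correlation between filtered test signal and each filtered template."""
    mat = _test_matrix(model, S)
    Et = model.ensemble.T
    x = (Et @ mat).ravel()
    out = np.empty(model.n_targets)
    for i, tmpl in enumerate(model.templates):
        y = (Et @ tmpl).ravel()
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(yc)
        out[i] = float(xc @ yc / denom) if denom > 0 else 0.0
    return out


def classify_trca(model: ItdmaModel, S) -> int:
    """Detected target (1-based): argmax correlation, lowest-index tie-break."""
    return int(np.argmax(trca_correlations(model, S))) + 1
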