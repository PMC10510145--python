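"""Evaluation statistics for affinity regression: MSE and concordance index.

The concordance index (CI) is the fraction of strictly ordered label
pairs whose predictions preserve the order, with tied predictions
scored 0.5 through the step function ``step_h``. Label ties contribute
no pair at all — they appear in neither the numerator nor the
normalisation constant Z.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError, UndefinedMetricError

__all__ = ["mse", "step_h", "concordance_index"]


def mse(predictions, labels) -> float:
    """Mean squared difference between two equal-length vectors."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise DataError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise DataError("MSE of empty vectors is undefined")
    return float(np.mean((p - y) ** 2))


def step_h(x: float) -> float:
    """Heaviside-style step: 1 for x > 0, 0.5 at exactly 0, 0 for x < 0."""
    if x > 0:
        return 1.0
    if x == 0:
        return 0.5
    return 0.0


def concordance_index(predictions, labels) -> float:
    """CI = (1/Z) Σ_{δ_i > δ_j} h(b_i − b_j) over strictly ordered label pairs.

    Vectorised over all pairs; ``Z`` counts pairs with strictly distinct
    labels. Raises :class:`UndefinedMetricError` when every label is
    tied (Z = 0).
    """
    b = np.asarray(predictions, dtype=np.float64)
    d = np.asarray(labels, dtype=np.float64)
    if b.shape != d.shape:
        raise DataError(f"length mismatch: {b.shape} vs {d.shape}")
    # ordered[i, j] == True where δ_i > δ_j
    ordered = d[:, None] > d[None, :]
    z = int(ordered.sum())
    if z == 0:
        raise UndefinedMetricError("all labels tied: concordance index undefined")
    diff = b[:, None] - b[None, :]
    h = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(h[ordered].sum() / z)
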