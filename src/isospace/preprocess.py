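"""Variance-stabilizing rescale of probe intensities.

Least-squares NMF assumes homoscedastic residuals, but probe residuals grow
with probe affinity.  Dividing each probe's intensities by the median of that
probe across all samples raised to the power 0.7 brings the residual variance
close to constant while retaining part of the affinity information (a full
median division, power 1.0, would discard it entirely).
"""

from __future__ import annotations

import numpy as np

from .model import ValidationError

DEFAULT_POWER = 0.7


def homoscedastic_rescale(Y, power: float = DEFAULT_POWER):
    """Divide each probe row by ``median_samples(row) ** power``.

    Returns ``(Y_scaled, scale)`` where ``scale`` is the positive per-probe
    divisor, so that ``undo_rescale(Y_scaled, scale)`` restores the input.

    Raises
    ------
    ValidationError
        If any probe row has a non-positive median (such a probe carries no
        usable scale information).
    """
    values = np.asarray(Y, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expected a 2-d probe matrix")
    med = np.median(values, axis=1)
    bad = np.nonzero(med <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"probe rows with non-positive median cannot be rescaled: "
            f"row indices {bad.tolist()}"
        )
    scale = med**power
    return values / scale[:, None], scale


def undo_rescale(X, scale) -> np.ndarray:
    """Multiply rows back by the per-probe scale (exact inverse of the rescale)."""
    X = np.asarray(X, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if X.shape[0] != scale.shape[0]:
        raise ValidationError(
            f"scale length {scale.shape[0]} does not match row count {X.shape[0]}"
        )
    return X * scale[:, None]
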