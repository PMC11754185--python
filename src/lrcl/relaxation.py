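"""Label relaxation: the sign ("luxury") matrix, relaxed targets, H update.

Strict one-hot targets Y are relaxed to Y~ = Y + U (*) H, where U is +1 on
true-class entries and -1 elsewhere and H >= 0 holds learned slack
magnitudes.  True-class targets can only grow above 1 and off-class targets
only drop below 0, so the relaxation enlarges class margins.
"""

from __future__ import annotations

import numpy as np

from lrcl.data import LabelMatrix


def build_luxury_matrix(Y: LabelMatrix | np.ndarray) -> np.ndarray:
    """Sign matrix U: +1 where Y_ij = 1, -1 where Y_ij = 0."""
    arr = Y.Y if isinstance(Y, LabelMatrix) else np.asarray(Y, dtype=float)
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("Y must be binary to build the sign matrix")
    if not np.all(arr.sum(axis=1) == 1):
        raise ValueError("Y must be one-hot (exactly one 1 per row)")
    return np.where(arr == 1.0, 1.0, -1.0)


def relax_labels(Y: np.ndarray, U: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Relaxed targets Y~ = Y + U (*) H (elementwise product)."""
    Y, U, H = (np.asarray(a, dtype=float) for a in (Y, U, H))
    if not (Y.shape == U.shape == H.shape):
        raise ValueError("Y, U, H must share a shape")
    if np.any(H < 0):
        raise ValueError("relaxation magnitudes H must be nonnegative")
    return Y + U * H


def update_H(fused_prediction: np.ndarray, Y: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Closed-form slack update H = max(U (*) (prediction - Y), 0).

    ``fused_prediction`` is the weight-fused score sum_k omega_k X_k Z_k.
    With view weights summing to one this is the exact minimizer of
    sum_k omega_k ||X_k Z_k - Y - U (*) H||_F^2 over H >= 0, entrywise.
    """
    fused_prediction, Y, U = (
        np.asarray(a, dtype=float) for a in (fused_prediction, Y, U)
    )
    if not (fused_prediction.shape == Y.shape == U.shape):
        raise ValueError("prediction, Y and U must share a shape")
    return np.maximum(U * (fused_prediction - Y), 0.0)
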