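"""Same-label similarity graphs and Laplacians for manifold regularization.

Within each view a Gaussian-kernel graph connects pairs of training samples
that share a class label; the associated Laplacian quadratic form penalizes
transforms that map same-label samples to distant points in the relaxed
label space, counteracting the overfitting that label relaxation invites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class ViewGraph:
    """Edge weights O and Laplacian L = D - O for one view.

    O is symmetric and nonnegative, zero across class boundaries and on the
    diagonal (self-loops excluded); L is positive semidefinite with zero row
    sums.
    """

    O: np.ndarray
    L: np.ndarray
    delta: float
    view_index: int = 0


def edge_weights(
    X: np.ndarray,
    labels: np.ndarray,
    delta: float | str = "auto",
    view_index: int = 0,
) -> ViewGraph:
    """Build the same-label Gaussian similarity graph of one view.

    O_ij = exp(-||x_i - x_j||^2 / delta) when label(i) == label(j) and
    i != j, else 0.  ``delta="auto"`` uses the mean squared Euclidean
    distance over same-label pairs as the kernel width.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to build a graph")

    sq = squareform(pdist(X, metric="sqeuclidean")) if n > 1 else np.zeros((1, 1))
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)

    if delta == "auto":
        pair_d = sq[same]
        if pair_d.size == 0:
            raise ValueError("no same-label pairs; cannot set delta automatically")
        delta_val = float(pair_d.mean())
        if delta_val == 0.0:
            delta_val = 1.0  # all same-label points coincide; any width works
    else:
        delta_val = float(delta)
        if delta_val <= 0:
            raise ValueError(f"kernel width delta must be positive, got {delta_val}")

    O = np.where(same, np.exp(-sq / delta_val), 0.0)
    O = (O + O.T) / 2.0  # exact symmetry against fp asymmetry in pdist layout
    L = np.diag(O.sum(axis=1)) - O
    return ViewGraph(O=O, L=L, delta=delta_val, view_index=view_index)


def laplacian_quadratic(Z: np.ndarray, X: np.ndarray, graph: ViewGraph) -> float:
    """tr(Z^T X^T L X Z) — the graph-smoothness penalty of a transform.

    Equals one half of the brute-force weighted pairwise sum
    sum_ij O_ij ||(XZ)_i - (XZ)_j||^2.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != Z.shape[0]:
        raise ValueError(
            f"non-conformable shapes: X is {X.shape}, Z is {Z.shape}"
        )
    M = X @ Z
    return float(np.trace(M.T @ graph.L @ M))
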