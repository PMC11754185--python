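"""Filter feature selection: Fisher score and Pearson score, per view.

Scores are computed on training rows only; the selected column sets are
then applied identically to every split.  The default combination averages
the two methods' ranks, since either pure ranking is also a valid choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import warnings

from lrcl.data import MultiViewDataset

_EPS = 1e-12


@dataclass
class FeatureRanking:
    """Per-view composite ranks and the selected column indices for one method."""

    ranks: list[np.ndarray]
    selected: list[np.ndarray]
    method: str
    n_keep: tuple[int, ...]


def fisher_score(X: np.ndarray, labels) -> np.ndarray:
    """Fisher score per feature: between-class over within-class scatter.

    F_j = sum_c n_c (mu_cj - mu_j)^2 / (sum_c n_c sigma2_cj + eps).
    Higher is more class-discriminative; a constant feature scores 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("Fisher score needs at least two classes")
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[labels == c]
        n_c = Xc.shape[0]
        num += n_c * (Xc.mean(axis=0) - mu) ** 2
        den += n_c * Xc.var(axis=0)
    return num / (den + _EPS)


def pearson_score(X: np.ndarray, labels) -> np.ndarray:
    """Absolute Pearson correlation of each feature with the 0/1 label.

    For more than two classes the score is the max over one-vs-rest
    encodings.  Constant features (or a constant label) score 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) == 2:
        encodings = [(labels == classes[1]).astype(float)]
    else:
        encodings = [(labels == c).astype(float) for c in classes]
    best = np.zeros(X.shape[1])
    for y in encodings:
        yc = y - y.mean()
        sy = np.sqrt(np.sum(yc**2))
        Xc = X - X.mean(axis=0)
        sx = np.sqrt(np.sum(Xc**2, axis=0))
        denom = sx * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, np.abs(Xc.T @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
        best = np.maximum(best, r)
    return best


def _ranks(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = best (highest score); ties broken by smaller feature index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def rank_features(X: np.ndarray, labels, method: str = "average_rank") -> np.ndarray:
    """Composite ranking of one view's features (lower rank = better)."""
    if method == "fisher":
        return _ranks(fisher_score(X, labels))
    if method == "pearson":
        return _ranks(pearson_score(X, labels))
    if method == "average_rank":
        return (_ranks(fisher_score(X, labels)) + _ranks(pearson_score(X, labels))) / 2.0
    raise ValueError(f"unknown feature scoring method {method!r}")


def select_features(
    dataset: MultiViewDataset,
    train_idx: np.ndarray,
    n_keep,
    method: str = "average_rank",
) -> tuple[MultiViewDataset, FeatureRanking]:
    """Keep the top-``n_keep`` features per view, ranked on training rows only.

    ``n_keep`` may be a single int or one int per view.  Requests beyond a
    view's width are capped with a warning.  Ties in the composite rank go
    to the smaller feature index.
    """
    if dataset.labels is None:
        raise ValueError("feature selection requires labels")
    K = dataset.n_views
    if np.isscalar(n_keep):
        n_keep = (int(n_keep),) * K
    n_keep = tuple(int(v) for v in n_keep)
    if len(n_keep) != K:
        raise ValueError("n_keep must be scalar or one value per view")
    train_idx = np.asarray(train_idx, dtype=int)
    y_tr = np.asarray(dataset.labels)[train_idx]

    all_ranks, selected, capped = [], [], []
    for k, X in enumerate(dataset.views):
        d_k = X.shape[1]
        keep = n_keep[k]
        if keep < 1:
            raise ValueError("n_keep must be at least 1")
        if keep > d_k:
            warnings.warn(
                f"view {k}: requested {keep} features but only {d_k} exist; keeping all",
                stacklevel=2,
            )
            keep = d_k
        capped.append(keep)
        ranks = rank_features(X[train_idx], y_tr, method)
        # stable top-k: sort by (rank, feature index)
        order = np.lexsort((np.arange(d_k), ranks))
        sel = np.sort(order[:keep])
        all_ranks.append(ranks)
        selected.append(sel)

    ranking = FeatureRanking(
        ranks=all_ranks, selected=selected, method=method, n_keep=tuple(capped)
    )
    return dataset.select_columns(selected), ranking
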