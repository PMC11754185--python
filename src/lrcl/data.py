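"""Multi-view data containers, table I/O, label encoding, splitting, scaling.

A *view* is one feature representation of the same set of samples (for the
motivating application: a radiomics table and a deep-feature table computed
from the same fundus photographs).  All downstream stages operate on a
:class:`MultiViewDataset` whose views are row-aligned by sample ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Raised when per-view tables cannot be aligned on sample IDs."""


@dataclass
class MultiViewDataset:
    """K feature matrices sharing N row-aligned samples.

    Parameters
    ----------
    views : list of (N, d_k) float arrays
        One matrix per view; rows aligned across views by ``sample_ids``.
    sample_ids : sequence of N unique identifiers.
    feature_names : per-view lists of column names (length d_k each).
    labels : optional array of N class identifiers; may be None at
        prediction time.
    """

    views: list[np.ndarray]
    sample_ids: list[str]
    feature_names: list[list[str]]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.views = [np.asarray(v, dtype=float) for v in self.views]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.views) < 1:
            raise ValueError("at least one view is required")
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        for k, v in enumerate(self.views):
            if v.ndim != 2:
                raise ValueError(f"view {k} is not a 2-D matrix")
            if v.shape[0] != n:
                raise ValueError(
                    f"view {k} has {v.shape[0]} rows but there are {n} sample IDs"
                )
            if v.shape[1] < 1:
                raise ValueError(f"view {k} has no features")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"view {k} contains non-finite values")
        if len(self.feature_names) != len(self.views):
            raise ValueError("feature_names must have one list per view")
        for k, (v, names) in enumerate(zip(self.views, self.feature_names)):
            if len(names) != v.shape[1]:
                raise ValueError(f"view {k}: feature name count != column count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length != number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    def subset(self, idx: np.ndarray) -> "MultiViewDataset":
        """Row subset (e.g. one split) preserving view structure."""
        idx = np.asarray(idx, dtype=int)
        return MultiViewDataset(
            views=[v[idx] for v in self.views],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=[list(n) for n in self.feature_names],
            labels=None if self.labels is None else self.labels[idx],
        )

    def select_columns(self, indices: Sequence[np.ndarray]) -> "MultiViewDataset":
        """Column subset per view (after feature selection)."""
        return MultiViewDataset(
            views=[v[:, np.asarray(ix, dtype=int)] for v, ix in zip(self.views, indices)],
            sample_ids=list(self.sample_ids),
            feature_names=[
                [names[j] for j in np.asarray(ix, dtype=int)]
                for names, ix in zip(self.feature_names, indices)
            ],
            labels=self.labels,
        )


@dataclass
class LabelMatrix:
    """One-hot label matrix Y (N x C) with a fixed, recorded class order."""

    Y: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D")
        if len(self.classes) != self.Y.shape[1] or self.Y.shape[1] < 2:
            raise ValueError("need C >= 2 recorded classes matching Y's columns")
        if not np.array_equal(self.Y, self.Y.astype(bool).astype(float)):
            raise ValueError("Y must be binary")
        if not np.all(self.Y.sum(axis=1) == 1):
            raise ValueError("each row of Y must have exactly one 1")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def decode(self) -> np.ndarray:
        """Inverse of :func:`encode_labels` (exact)."""
        idx = np.argmax(self.Y, axis=1)
        return np.asarray([self.classes[i] for i in idx])


@dataclass
class SplitPlan:
    """Disjoint train/validation/test index sets covering all samples."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[float, float, float]
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")


def load_views(
    paths: Sequence[str | Path],
    label_path: str | Path | None = None,
    require_labels: bool = True,
) -> MultiViewDataset:
    """Load per-view delimited tables and align rows on the sample-ID column.

    Each table must have a header row whose first column is the sample ID;
    the remaining columns are numeric features.  Comma or tab delimiters are
    auto-detected.  Rows are aligned on the *intersection* of IDs across all
    views (and the label table, if given), sorted by ID; dropped IDs are
    reported with a warning rather than an error.
    """
    frames = []
    for p in paths:
        df = _read_table(Path(p))
        frames.append(df)

    common = set(frames[0].index)
    for df in frames[1:]:
        common &= set(df.index)

    label_series = None
    if label_path is not None:
        ldf = _read_table(Path(label_path), numeric=False)
        if ldf.shape[1] != 1:
            raise ValueError(
                f"label table {label_path} must have exactly two columns "
                "(sample_id, label)"
            )
        label_series = ldf.iloc[:, 0]
        if require_labels:
            missing = sorted(common - set(label_series.index))
            if missing:
                raise AlignmentError(
                    f"label file is missing samples: {', '.join(map(str, missing))}"
                )
        common &= set(label_series.index)

    if not common:
        raise AlignmentError("no sample IDs are shared across all input tables")

    ids = sorted(common)
    dropped = sorted(
        set().union(*(set(df.index) for df in frames)) - common
    )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) not present in every table: "
            f"{', '.join(map(str, dropped))}",
            stacklevel=2,
        )

    views = [df.loc[ids].to_numpy(dtype=float) for df in frames]
    names = [list(df.columns) for df in frames]
    labels = label_series.loc[ids].to_numpy() if label_series is not None else None
    return MultiViewDataset(views=views, sample_ids=ids, feature_names=names, labels=labels)


def _read_table(path: Path, numeric: bool = True) -> pd.DataFrame:
    """Read a delimited table, auto-detecting comma/tab, ID column first."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an ID column plus at least one data column")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups}")
    df = df.set_index(id_col)
    if numeric:
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r}, row {row!r}"
                ) from exc
    return df


def encode_labels(raw_labels: Sequence) -> LabelMatrix:
    """One-hot encode class identifiers with lexicographic class order."""
    raw = np.asarray(raw_labels)
    classes = sorted(set(raw.tolist()))
    if len(classes) < 2:
        raise ValueError(
            f"need at least two distinct classes, got only {classes!r}"
        )
    lookup = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(raw), len(classes)))
    for i, lab in enumerate(raw.tolist()):
        Y[i, lookup[lab]] = 1.0
    return LabelMatrix(Y=Y, classes=classes)


def stratified_split(
    dataset: MultiViewDataset,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitPlan:
    """Deterministic stratified train/validation/test split.

    Global partition sizes are ``floor(N * r)`` for validation and test with
    the remainder assigned to train; per-class counts stay within one sample
    of exact proportionality.  Identical (dataset, ratios, seed) always gives
    the identical plan.
    """
    if dataset.labels is None:
        raise ValueError("stratified split requires labels")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.asarray(dataset.labels)
    classes, counts = np.unique(labels, return_counts=True)
    for c, n_c in zip(classes, counts):
        if n_c < 3:
            raise ValueError(
                f"class {c!r} has only {n_c} member(s); need at least 3 "
                "to place one in each partition"
            )
    n = dataset.n_samples
    rng = np.random.default_rng(seed)

    # shuffle within each class, deterministically by class order
    per_class: dict = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        per_class[c] = rng.permutation(idx)

    val_idx = _allocate(per_class, classes, ratios[1], int(np.floor(n * ratios[1])), offset={})
    taken = {c: len([i for i in val_idx if labels[i] == c]) for c in classes}
    test_idx = _allocate(
        per_class, classes, ratios[2], int(np.floor(n * ratios[2])), offset=taken
    )
    chosen = set(val_idx) | set(test_idx)
    train_idx = np.asarray([i for i in range(n) if i not in chosen], dtype=int)
    return SplitPlan(
        train_idx=train_idx,
        val_idx=np.sort(val_idx),
        test_idx=np.sort(test_idx),
        ratios=tuple(ratios),
        seed=seed,
    )


def _allocate(per_class, classes, ratio, target, offset) -> np.ndarray:
    """Pick `target` indices, floor(n_c*ratio) per class then largest remainders."""
    base, frac = {}, {}
    for c in classes:
        exact = len(per_class[c]) * ratio
        base[c] = int(np.floor(exact))
        frac[c] = exact - base[c]
    short = target - sum(base.values())
    # distribute the remainder by largest fractional part, ties by class order
    order = sorted(classes, key=lambda c: (-frac[c], list(classes).index(c)))
    for c in order[:max(short, 0)]:
        base[c] += 1
    out = []
    for c in classes:
        start = offset.get(c, 0)
        out.extend(per_class[c][start : start + base[c]])
    return np.asarray(out, dtype=int)


@dataclass
class Standardizer:
    """Per-view z-scoring parameters estimated on the training split only.

    Zero-variance (constant) training columns get scale 1 and are flagged in
    ``constant_features`` rather than failing.
    """

    means: list[np.ndarray] = field(default_factory=list)
    scales: list[np.ndarray] = field(default_factory=list)
    constant_features: list[np.ndarray] = field(default_factory=list)

    def fit(self, views: Sequence[np.ndarray]) -> "Standardizer":
        self.means, self.scales, self.constant_features = [], [], []
        for X in views:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)  # population sd, matching two-point (0,2)->(-1,1)
            const = sd == 0
            sd = np.where(const, 1.0, sd)
            self.means.append(mu)
            self.scales.append(sd)
            self.constant_features.append(np.flatnonzero(const))
        return self

    def transform(self, views: Sequence[np.ndarray]) -> list[np.ndarray]:
        if not self.means:
            raise RuntimeError("Standardizer not fitted")
        return [(X - mu) / sd for X, mu, sd in zip(views, self.means, self.scales)]


def standardize(
    dataset: MultiViewDataset, plan: SplitPlan
) -> tuple[MultiViewDataset, Standardizer]:
    """Z-score every view using train-split statistics, applied to all rows."""
    scaler = Standardizer().fit([v[plan.train_idx] for v in dataset.views])
    new_views = scaler.transform(dataset.views)
    out = MultiViewDataset(
        views=new_views,
        sample_ids=list(dataset.sample_ids),
        feature_names=[list(n) for n in dataset.feature_names],
        labels=dataset.labels,
    )
    return out, scaler
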