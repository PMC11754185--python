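"""Synthetic multi-view data with controllable shared and private signal.

The generator emulates the structure the collaborative model targets: a
latent class-informative factor *shared* across views (the "consistent
pattern" the consistency regularizer exploits), a class-informative factor
*private* to each view, Gaussian noise, and pure-noise distractor columns
that give the feature-selection step real work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lrcl.data import MultiViewDataset


@dataclass
class GeneratorSpec:
    """Knobs of the synthetic two-class multi-view generator.

    N : number of samples (default 200).
    d : informative feature count per view (default (40, 50), mirroring a
        radiomics-sized and a deep-feature-sized view).
    K : number of views (must match len(d)).
    sep : class separation — magnitude of the mean shift of the latent
        factors between classes (default 1.0).
    rho_consist : fraction of informative signal carried by the shared
        (cross-view consistent) latent factor, in [0, 1] (default 0.7).
    noise_sd : scale of the additive Gaussian feature noise (default 1.0).
    class_balance : fraction of positive samples (default 0.5).
    distractor_multiplier : pure-noise columns appended per view, as a
        multiple of the informative count (default 2).
    """

    N: int = 200
    d: tuple[int, ...] = (40, 50)
    K: int = 2
    sep: float = 1.0
    rho_consist: float = 0.7
    noise_sd: float = 1.0
    class_balance: float = 0.5
    distractor_multiplier: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("need at least 4 samples")
        if self.K != len(self.d):
            raise ValueError("K must equal the number of per-view dimensions")
        if any(dk < 1 for dk in self.d):
            raise ValueError("every view needs at least one informative feature")
        if not 0.0 <= self.rho_consist <= 1.0:
            raise ValueError("rho_consist must be in [0, 1]")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be strictly between 0 and 1")
        if self.noise_sd < 0 or self.sep < 0:
            raise ValueError("sep and noise_sd must be nonnegative")
        if self.distractor_multiplier < 0:
            raise ValueError("distractor_multiplier must be nonnegative")


def generate(spec: GeneratorSpec) -> MultiViewDataset:
    """Draw one multi-view dataset; the same spec and seed is bitwise stable.

    Per view k:  X_k = rho * s a_k^T + (1 - rho) * v_k b_k^T + noise,
    where s is the shared latent factor, v_k a view-private one (both with
    class-mean shift +-sep), and a_k, b_k fixed unit loading vectors.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.N) < spec.class_balance).astype(int)
    if y.min() == y.max():  # degenerate draw: force both classes, deterministically
        y[0] = 1 - y[0]
    sign = 2.0 * y - 1.0

    s = spec.sep * sign + rng.standard_normal(spec.N)

    views, names = [], []
    for k, d_k in enumerate(spec.d):
        a = rng.standard_normal(d_k)
        a /= np.linalg.norm(a)
        b = rng.standard_normal(d_k)
        b /= np.linalg.norm(b)
        v = spec.sep * sign + rng.standard_normal(spec.N)
        X = (
            spec.rho_consist * np.outer(s, a)
            + (1.0 - spec.rho_consist) * np.outer(v, b)
            + spec.noise_sd * rng.standard_normal((spec.N, d_k))
        )
        n_noise = spec.distractor_multiplier * d_k
        if n_noise:
            X = np.hstack([X, rng.standard_normal((spec.N, n_noise))])
        views.append(X)
        names.append(
            [f"v{k}_f{j}" for j in range(d_k)]
            + [f"v{k}_noise{j}" for j in range(n_noise)]
        )

    width = len(str(spec.N))
    ids = [f"s{i:0{width}d}" for i in range(1, spec.N + 1)]
    return MultiViewDataset(views=views, sample_ids=ids, feature_names=names, labels=y)


# A frozen, hand-checkable two-view instance used in documentation and in
# regression tests of every update formula.  Values are literal on purpose.
_WORKED_X1 = np.array(
    [
        [1.2, 0.4, -0.3],
        [0.9, 0.1, 0.2],
        [1.1, -0.2, 0.5],
        [0.8, 0.3, -0.1],
        [-1.0, 0.2, 0.4],
        [-0.7, -0.4, -0.2],
        [-1.2, 0.1, 0.3],
        [-0.9, -0.3, -0.5],
    ]
)
_WORKED_X2 = np.array(
    [
        [0.5, 1.0, 0.2],
        [0.7, 0.8, -0.1],
        [0.4, 1.2, 0.3],
        [0.6, 0.9, 0.0],
        [-0.5, -0.8, 0.1],
        [-0.3, -1.1, -0.2],
        [-0.6, -0.9, 0.4],
        [-0.4, -1.0, -0.3],
    ]
)
_WORKED_LABELS = np.array([0, 0, 0, 0, 1, 1, 1, 1])


def generate_worked_instance() -> MultiViewDataset:
    """A tiny frozen N=8, K=2, d=(3,3) dataset with clean class structure."""
    return MultiViewDataset(
        views=[_WORKED_X1.copy(), _WORKED_X2.copy()],
        sample_ids=[f"w{i}" for i in range(1, 9)],
        feature_names=[["x1", "x2", "x3"], ["y1", "y2", "y3"]],
        labels=_WORKED_LABELS.copy(),
    )
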