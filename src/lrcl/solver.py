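"""Alternating closed-form solver for label-relaxation collaborative learning.

The model learns, for each of K feature views, a linear transform Z_k into
a relaxed label space, together with simplex view weights omega and a
nonnegative relaxation matrix H, by minimizing

    J = sum_k [ omega_k * ( ||X_k Z_k - Ytilde||_F^2
                            + beta * ||X_k Z_k - C_k||_F^2 )
                + omega_k * ln(omega_k)
                + alpha * tr(Z_k^T X_k^T L_k X_k Z_k) ]

subject to H >= 0 and sum_k omega_k = 1, where Ytilde = Y + U (*) H is the
relaxed label matrix, C_k is the ridge-prior consensus of the other views,
and L_k the same-label graph Laplacian of view k.  Each block (Z_k, omega,
H) has an exact closed-form minimizer, so alternating updates descend J
monotonically; iteration stops when the summed Frobenius change of the Z_k
falls below ``tol``.

The entropy term makes the optimal view weights a softmax of negative
per-view losses ("Shannon-entropy view weighting"): views that fit the
relaxed labels and agree with the cross-view consensus better receive
larger weight automatically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from lrcl.data import LabelMatrix, encode_labels
from lrcl.graph import ViewGraph, edge_weights, laplacian_quadratic
from lrcl.relaxation import build_luxury_matrix, relax_labels, update_H


@dataclass
class FitConfig:
    """Hyperparameters and numerical controls of the solver.

    alpha
        Weight of the Laplacian manifold penalty (>= 0).
    beta
        Weight of the cross-view consistency penalty (>= 0).
    delta
        Gaussian kernel width of the same-label graphs, or ``"auto"`` for
        the mean squared same-label pairwise distance.
    ridge_lambda
        Ridge penalty of the per-view prior transforms P_k.
    jitter
        Small diagonal added inside every matrix inverse; keeps the update
        well-posed when d_k exceeds the number of training samples.
    tol
        Convergence threshold on sum_k ||Z_k(t) - Z_k(t-1)||_F.
    init
        ``"deterministic"``: omega uniform, H = 0.  ``"random"``: omega from
        a symmetric Dirichlet and H ~ |N(0, 0.01)|, seeded.
    learn_relaxation
        If False, H stays fixed at 0 (strict one-hot targets).
    """

    alpha: float = 1.0
    beta: float = 1.0
    delta: float | str = "auto"
    ridge_lambda: float = 1.0
    jitter: float = 1e-8
    tol: float = 1e-8
    max_iter: int = 200
    seed: int = 0
    init: str = "deterministic"
    learn_relaxation: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.alpha < 0 or self.beta < 0 or self.ridge_lambda < 0 or self.jitter < 0:
            raise ValueError("alpha, beta, ridge_lambda and jitter must be nonnegative")
        if self.init not in ("deterministic", "random"):
            raise ValueError("init must be 'deterministic' or 'random'")


@dataclass
class ModelState:
    """Everything the solver learns plus its convergence diagnostics."""

    Z: list[np.ndarray]
    omega: np.ndarray
    P: list[np.ndarray]
    C_targets: list[np.ndarray]
    graphs: list[ViewGraph]
    U: np.ndarray
    H: np.ndarray
    iteration: int = 0
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False


def ridge_prior(X: np.ndarray, Y: np.ndarray, ridge_lambda: float) -> np.ndarray:
    """Ridge transform P = (X^T X + lambda I)^-1 X^T Y, the per-view prior.

    Computed once on the training split and frozen; it encodes what each
    view alone predicts and anchors the cross-view consistency targets.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")
    d = X.shape[1]
    G = X.T @ X + ridge_lambda * np.eye(d)
    if ridge_lambda == 0 and np.linalg.matrix_rank(X.T @ X) < d:
        raise np.linalg.LinAlgError(
            "X^T X is singular at ridge_lambda=0; set ridge_lambda > 0"
        )
    return scipy.linalg.solve(G, X.T @ Y, assume_a="pos")


def consensus_target(
    X_all: Sequence[np.ndarray], P_all: Sequence[np.ndarray], k: int
) -> np.ndarray:
    """Consensus C_k = mean over other views t of their prior predictions X_t P_t."""
    K = len(X_all)
    if K < 2:
        raise ValueError("consensus targets need at least two views")
    terms = [X_all[t] @ P_all[t] for t in range(K) if t != k]
    return sum(terms) / (K - 1)


def update_Z(
    X: np.ndarray,
    Y_relaxed: np.ndarray,
    C: np.ndarray,
    L: np.ndarray,
    omega_k: float,
    alpha: float,
    beta: float,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Closed-form per-view transform update.

    Z_k = [omega_k (1+beta) X^T X + alpha X^T L X + jitter I]^-1
          omega_k X^T (Ytilde + beta C) — the exact stationary point of J
    in Z_k with the other blocks fixed.
    """
    if omega_k <= 0:
        raise ValueError("omega_k must be positive")
    d = X.shape[1]
    A = omega_k * (1.0 + beta) * (X.T @ X) + alpha * (X.T @ L @ X)
    if jitter > 0:
        A = A + jitter * np.eye(d)
    b = omega_k * (X.T @ (Y_relaxed + beta * C))
    try:
        return scipy.linalg.solve(A, b, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular system in the Z update; set jitter > 0 (default 1e-8)"
        ) from exc


def update_weights(errors: Sequence[float]) -> np.ndarray:
    """Entropy-regularized view weights: omega = softmax(-E).

    E_k is the per-view loss ||X_k Z_k - Ytilde||_F^2
    + beta ||X_k Z_k - C_k||_F^2.  The softmax is computed with a max
    shift, so very large losses cannot underflow all weights to zero.
    This is the exact minimizer of sum_k (omega_k E_k + omega_k ln omega_k)
    on the probability simplex.
    """
    E = np.asarray(errors, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValueError(f"non-finite per-view errors: {E}")
    shifted = -(E - E.min())
    w = np.exp(shifted)
    return w / w.sum()


def per_view_errors(
    X_all: Sequence[np.ndarray],
    Z_all: Sequence[np.ndarray],
    Y_relaxed: np.ndarray,
    C_all: Sequence[np.ndarray],
    beta: float,
) -> np.ndarray:
    """E_k = ||X_k Z_k - Ytilde||_F^2 + beta ||X_k Z_k - C_k||_F^2."""
    out = []
    for X, Z, C in zip(X_all, Z_all, C_all):
        M = X @ Z
        e = float(np.sum((M - Y_relaxed) ** 2))
        if beta > 0:
            e += beta * float(np.sum((M - C) ** 2))
        out.append(e)
    return np.asarray(out)


def objective(
    X_all: Sequence[np.ndarray],
    state: ModelState,
    Y: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Evaluate J at the current state.  Always >= -ln K."""
    Y_relaxed = relax_labels(Y, state.U, state.H)
    E = per_view_errors(X_all, state.Z, Y_relaxed, state.C_targets, beta)
    J = float(np.dot(state.omega, E) + np.sum(state.omega * np.log(state.omega)))
    if alpha > 0:
        for X, Z, g in zip(X_all, state.Z, state.graphs):
            J += alpha * laplacian_quadratic(Z, X, g)
    return J


def fit(
    views: Sequence[np.ndarray],
    labels: Sequence,
    config: FitConfig,
    monitor: Callable[[int, ModelState], None] | None = None,
) -> tuple[ModelState, LabelMatrix]:
    """Run the alternating solver on training views and labels.

    Per outer iteration: update every Z_k, then the view weights omega,
    then the slack H (the weight update precedes H so that the H minimizer's
    sum-to-one premise holds).  The objective is recorded after every block
    update; convergence is declared when sum_k ||Z_k(t)-Z_k(t-1)||_F < tol.

    ``monitor`` (if given) is called as ``monitor(iteration, state)`` after
    each outer iteration, e.g. to trace train/test AUC.
    """
    X_all = [np.asarray(v, dtype=float) for v in views]
    K = len(X_all)
    lm = encode_labels(labels)
    Y = lm.Y
    N, C = Y.shape

    beta = config.beta
    if K == 1 and beta > 0:
        warnings.warn(
            "consistency regularization needs at least two views; "
            "proceeding with beta = 0",
            stacklevel=2,
        )
        beta = 0.0

    graphs = [
        edge_weights(X, np.asarray(labels), delta=config.delta, view_index=k)
        for k, X in enumerate(X_all)
    ]
    P_all = [ridge_prior(X, Y, config.ridge_lambda) for X in X_all]
    if K >= 2 and beta > 0:
        C_all = [consensus_target(X_all, P_all, k) for k in range(K)]
    else:
        C_all = [np.zeros((N, C)) for _ in range(K)]

    U = build_luxury_matrix(lm)
    rng = np.random.default_rng(config.seed)
    if config.init == "random":
        omega = rng.dirichlet(np.ones(K))
        H = np.abs(rng.normal(0.0, 0.1, size=(N, C))) if config.learn_relaxation else np.zeros((N, C))
    else:
        omega = np.full(K, 1.0 / K)
        H = np.zeros((N, C))

    state = ModelState(
        Z=[np.zeros((X.shape[1], C)) for X in X_all],
        omega=omega,
        P=P_all,
        C_targets=C_all,
        graphs=graphs,
        U=U,
        H=H,
    )
    state.objective_trace.append(objective(X_all, state, Y, config.alpha, beta))

    for it in range(1, config.max_iter + 1):
        Z_prev = [Z.copy() for Z in state.Z]
        Y_relaxed = relax_labels(Y, U, state.H)

        for k in range(K):
            state.Z[k] = update_Z(
                X_all[k], Y_relaxed, C_all[k], graphs[k].L,
                float(state.omega[k]), config.alpha, beta, config.jitter,
            )
        state.objective_trace.append(objective(X_all, state, Y, config.alpha, beta))

        E = per_view_errors(X_all, state.Z, Y_relaxed, C_all, beta)
        state.omega = update_weights(E)
        state.objective_trace.append(objective(X_all, state, Y, config.alpha, beta))

        if config.learn_relaxation:
            fused = sum(w * (X @ Z) for w, X, Z in zip(state.omega, X_all, state.Z))
            state.H = update_H(fused, Y, U)
        state.objective_trace.append(objective(X_all, state, Y, config.alpha, beta))

        state.iteration = it
        if not np.isfinite(state.objective_trace[-1]):
            terms = per_view_errors(X_all, state.Z, relax_labels(Y, U, state.H), C_all, beta)
            raise FloatingPointError(
                f"objective became non-finite at iteration {it}; "
                f"per-view errors {terms}, omega {state.omega}"
            )
        if monitor is not None:
            monitor(it, state)

        dz = sum(float(np.linalg.norm(Z - Zp)) for Z, Zp in zip(state.Z, Z_prev))
        if dz < config.tol:
            state.converged = True
            break

    return state, lm


def predict_scores(
    views: Sequence[np.ndarray], Z: Sequence[np.ndarray], omega: np.ndarray
) -> np.ndarray:
    """Fused score matrix S = sum_k omega_k X_k Z_k (rows: samples, cols: classes)."""
    S = None
    for k, (X, Zk) in enumerate(zip(views, Z)):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != Zk.shape[0]:
            raise ValueError(
                f"view {k}: got {X.shape[1]} features, model expects {Zk.shape[0]}"
            )
        term = omega[k] * (X @ Zk)
        S = term if S is None else S + term
    return S


class LRCLClassifier:
    """Scikit-learn-style estimator wrapping the alternating solver.

    Parameters mirror :class:`FitConfig`.  ``fit`` takes a list of per-view
    training matrices (same rows, aligned) plus labels; ``predict`` and
    ``decision_function`` take per-view matrices with the training feature
    dimensions.

    For binary problems the decision score is S[:, positive] -
    S[:, negative] with the lexicographically larger class treated as
    positive unless ``pos_label`` says otherwise.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        beta: float = 1.0,
        delta: float | str = "auto",
        ridge_lambda: float = 1.0,
        jitter: float = 1e-8,
        tol: float = 1e-8,
        max_iter: int = 200,
        seed: int = 0,
        init: str = "deterministic",
        learn_relaxation: bool = True,
    ):
        self.alpha = alpha
        self.beta = beta
        self.delta = delta
        self.ridge_lambda = ridge_lambda
        self.jitter = jitter
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.init = init
        self.learn_relaxation = learn_relaxation

    def _config(self) -> FitConfig:
        return FitConfig(
            alpha=self.alpha,
            beta=self.beta,
            delta=self.delta,
            ridge_lambda=self.ridge_lambda,
            jitter=self.jitter,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.seed,
            init=self.init,
            learn_relaxation=self.learn_relaxation,
        )

    def fit(
        self,
        views: Sequence[np.ndarray],
        labels: Sequence,
        monitor: Callable[[int, ModelState], None] | None = None,
    ) -> "LRCLClassifier":
        self.state_, self.label_matrix_ = fit(views, labels, self._config(), monitor)
        self.classes_ = list(self.label_matrix_.classes)
        return self

    def predict_scores(self, views: Sequence[np.ndarray]) -> np.ndarray:
        self._check_fitted()
        return predict_scores(views, self.state_.Z, self.state_.omega)

    def decision_function(
        self, views: Sequence[np.ndarray], pos_label=None
    ) -> np.ndarray:
        """Continuous binary decision score (positive minus negative column)."""
        self._check_fitted()
        if len(self.classes_) != 2:
            raise ValueError("decision_function is defined for binary problems only")
        pos = self.classes_[1] if pos_label is None else pos_label
        j_pos = self.classes_.index(pos)
        S = self.predict_scores(views)
        return S[:, j_pos] - S[:, 1 - j_pos]

    def predict(self, views: Sequence[np.ndarray]) -> np.ndarray:
        """Class assignments: argmax over fused scores, ties to the lowest index."""
        S = self.predict_scores(views)
        idx = np.argmax(S, axis=1)
        return np.asarray([self.classes_[i] for i in idx])

    def _check_fitted(self) -> None:
        if not hasattr(self, "state_"):
            raise RuntimeError("classifier is not fitted")

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write Z_k, P_k, omega, classes and config as delimited text."""
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for k, (Z, P) in enumerate(zip(self.state_.Z, self.state_.P)):
            np.savetxt(d / f"Z_view{k}.tsv", Z, delimiter="\t", fmt="%.17g")
            np.savetxt(d / f"P_view{k}.tsv", P, delimiter="\t", fmt="%.17g")
        np.savetxt(d / "omega.tsv", self.state_.omega, delimiter="\t", fmt="%.17g")
        meta = {
            "classes": [str(c) for c in self.classes_],
            "n_views": len(self.state_.Z),
            "iteration": self.state_.iteration,
            "converged": bool(self.state_.converged),
            "config": {
                "alpha": self.alpha,
                "beta": self.beta,
                "delta": self.delta,
                "ridge_lambda": self.ridge_lambda,
                "jitter": self.jitter,
                "tol": self.tol,
                "max_iter": self.max_iter,
                "seed": self.seed,
                "init": self.init,
                "learn_relaxation": self.learn_relaxation,
            },
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "LRCLClassifier":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        clf = cls(**meta["config"])
        K = meta["n_views"]
        Z = [np.atleast_2d(np.loadtxt(d / f"Z_view{k}.tsv", delimiter="\t")) for k in range(K)]
        P = [np.atleast_2d(np.loadtxt(d / f"P_view{k}.tsv", delimiter="\t")) for k in range(K)]
        omega = np.atleast_1d(np.loadtxt(d / "omega.tsv", delimiter="\t"))
        classes = meta["classes"]
        N_C = Z[0].shape[1]
        state = ModelState(
            Z=Z, omega=omega, P=P, C_targets=[], graphs=[],
            U=np.zeros((0, N_C)), H=np.zeros((0, N_C)),
            iteration=meta["iteration"], converged=meta["converged"],
        )
        clf.state_ = state
        clf.classes_ = classes
        clf.label_matrix_ = None
        return clf
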