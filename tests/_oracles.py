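"""Independent numerical oracles the tests check the closed forms against.

Everything here avoids the package's own update formulas: brute-force
double sums, pairwise enumeration, stacked least squares via QR, and
black-box constrained minimization of the very same objective.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.optimize


def brute_force_pairwise(O: np.ndarray, M: np.ndarray) -> float:
    """sum_ij O_ij ||M_i - M_j||^2 by explicit double loop."""
    n = O.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += O[i, j] * float(np.sum((M[i] - M[j]) ** 2))
    return total


def pairwise_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the proportion of concordant positive-negative pairs (ties 1/2)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return 100.0 * wins / (len(pos) * len(neg))


def entrywise_H_oracle(fused: np.ndarray, Y: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Minimize (m_ij - u_ij h)^2 over h >= 0 for each entry independently.

    m = fused - Y.  The 1-D minimizer is h* = u*m clipped at zero (scalar
    quadratic), evaluated here by bounded scalar minimization, not by the
    package's formula.
    """
    m = fused - Y
    H = np.zeros_like(m)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            f = lambda h: (m[i, j] - U[i, j] * h) ** 2
            res = scipy.optimize.minimize_scalar(
                f, bounds=(0.0, abs(m[i, j]) + 1.0), method="bounded",
                options={"xatol": 1e-14},
            )
            H[i, j] = res.x if f(res.x) < f(0.0) else 0.0
    return H


def simplex_weight_oracle(E: np.ndarray) -> np.ndarray:
    """Minimize sum_k (w_k E_k + w_k ln w_k) on the simplex numerically."""
    K = len(E)

    def obj(w):
        w = np.clip(w, 1e-300, None)
        return float(np.dot(w, E) + np.sum(w * np.log(w)))

    def grad(w):
        w = np.clip(w, 1e-300, None)
        return E + np.log(w) + 1.0

    res = scipy.optimize.minimize(
        obj,
        x0=np.full(K, 1.0 / K),
        jac=grad,
        method="trust-constr",
        bounds=scipy.optimize.Bounds(1e-14, 1.0),
        constraints=scipy.optimize.LinearConstraint(np.ones((1, K)), 1.0, 1.0),
        options={"gtol": 1e-13, "xtol": 1e-14, "maxiter": 2000},
    )
    return res.x


def simplex_weight_oracle_2view(E: np.ndarray) -> np.ndarray:
    """Two-view weight problem reduced to bounded scalar minimization.

    On the 2-simplex the problem is f(t) = t E0 + (1-t) E1 + t ln t +
    (1-t) ln(1-t) over t in (0, 1); Brent's method resolves minimizers
    arbitrarily close to the boundary, where barrier methods stall.
    """
    E0, E1 = float(E[0]), float(E[1])

    def f(t):
        return t * E0 + (1 - t) * E1 + t * np.log(t) + (1 - t) * np.log(1 - t)

    res = scipy.optimize.minimize_scalar(
        f, bounds=(1e-300, 1.0 - 1e-16), method="bounded", options={"xatol": 1e-15}
    )
    return np.array([res.x, 1.0 - res.x])


def stacked_ls_Z_oracle(X, T_label, C_target, L, omega_k, alpha, beta):
    """Single-block Z minimizer as one stacked least-squares problem via QR.

    Minimizing omega(||XZ-T||^2 + beta||XZ-C||^2) + alpha tr(Z'X'LXZ) is the
    least-squares problem with stacked design [sqrt(omega) X; sqrt(omega
    beta) X; sqrt(alpha) L^(1/2) X] and targets [sqrt(omega) T; sqrt(omega
    beta) C; 0], solved here by lstsq (QR/SVD), not normal equations.
    """
    evals, evecs = np.linalg.eigh((L + L.T) / 2.0)
    Lhalf = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    rows = [np.sqrt(omega_k) * X]
    targets = [np.sqrt(omega_k) * T_label]
    if beta > 0:
        rows.append(np.sqrt(omega_k * beta) * X)
        targets.append(np.sqrt(omega_k * beta) * C_target)
    if alpha > 0:
        rows.append(np.sqrt(alpha) * (Lhalf @ X))
        targets.append(np.zeros_like(T_label))
    A = np.vstack(rows)
    b = np.vstack(targets)
    Z, *_ = np.linalg.lstsq(A, b, rcond=None)
    return Z


def profiled_objective(params, X_all, Y, U, C_all, L_all, alpha, beta, shapes, N, Cdim):
    """J with the view weights profiled out: -ln sum_k exp(-E_k) + alpha traces."""
    Z_all, H = _unpack(params, shapes, N, Cdim)
    Yr = Y + U * H
    E = []
    for X, Z, Ct in zip(X_all, Z_all, C_all):
        M = X @ Z
        e = float(np.sum((M - Yr) ** 2))
        if beta > 0:
            e += beta * float(np.sum((M - Ct) ** 2))
        E.append(e)
    E = np.asarray(E)
    m = E.min()
    J = m - np.log(np.sum(np.exp(-(E - m))))
    if alpha > 0:
        for X, Z, L in zip(X_all, Z_all, L_all):
            M = X @ Z
            J += alpha * float(np.trace(M.T @ L @ M))
    return J


def profiled_gradient(params, X_all, Y, U, C_all, L_all, alpha, beta, shapes, N, Cdim):
    Z_all, H = _unpack(params, shapes, N, Cdim)
    Yr = Y + U * H
    E, resid = [], []
    for X, Z, Ct in zip(X_all, Z_all, C_all):
        M = X @ Z
        r = M - Yr
        e = float(np.sum(r**2))
        if beta > 0:
            e += beta * float(np.sum((M - Ct) ** 2))
        E.append(e)
        resid.append((M, r))
    E = np.asarray(E)
    w = np.exp(-(E - E.min()))
    w /= w.sum()

    gZ, gH = [], np.zeros_like(H)
    for k, (X, Z, Ct, L) in enumerate(zip(X_all, Z_all, C_all, L_all)):
        M, r = resid[k]
        g = w[k] * (2.0 * X.T @ r)
        if beta > 0:
            g += w[k] * beta * (2.0 * X.T @ (M - Ct))
        if alpha > 0:
            g += alpha * 2.0 * (X.T @ (L @ M))
        gZ.append(g)
        gH += w[k] * (-2.0 * r * U)
    return np.concatenate([g.ravel() for g in gZ] + [gH.ravel()])


def _unpack(params, shapes, N, Cdim):
    Z_all, off = [], 0
    for d, c in shapes:
        Z_all.append(params[off : off + d * c].reshape(d, c))
        off += d * c
    H = params[off:].reshape(N, Cdim)
    return Z_all, H


def blackbox_joint_minimum(X_all, Y, U, C_all, L_all, alpha, beta, n_starts=3):
    """Minimize the profiled objective over (Z_1..Z_K, H >= 0) with L-BFGS-B.

    The soft-min view weighting makes the surface badly conditioned, so a
    single quasi-Newton run can stall: each start is polished by restarting
    L-BFGS-B from its own endpoint (resetting the Hessian memory) until the
    value stops improving, and the best of several starts is returned.
    """
    shapes = [(X.shape[1], Y.shape[1]) for X in X_all]
    N, Cdim = Y.shape
    nz = sum(d * c for d, c in shapes)
    bounds = [(None, None)] * nz + [(0.0, None)] * (N * Cdim)
    args = (X_all, Y, U, C_all, L_all, alpha, beta, shapes, N, Cdim)
    rng = np.random.default_rng(0)
    starts = [np.zeros(nz + N * Cdim)]
    starts += [
        np.concatenate(
            [0.3 * rng.standard_normal(nz), np.abs(0.1 * rng.standard_normal(N * Cdim))]
        )
        for _ in range(n_starts - 1)
    ]

    best_fun, best_res = np.inf, None
    for x0 in starts:
        x, fun = x0, np.inf
        for _ in range(25):  # polish by restarts until no further progress
            res = scipy.optimize.minimize(
                profiled_objective, x, jac=profiled_gradient, args=args,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 20000, "maxfun": 100000, "ftol": 0.0,
                         "gtol": 1e-12, "maxcor": 50},
            )
            x = res.x
            if res.fun >= fun - 1e-12 * max(1.0, abs(fun)):
                fun = min(fun, res.fun)
                break
            fun = res.fun
        if fun < best_fun:
            best_fun, best_res = fun, res
    return best_fun, best_res
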