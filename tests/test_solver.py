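import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from lrcl.data import encode_labels
from lrcl.graph import edge_weights
from lrcl.relaxation import build_luxury_matrix, relax_labels, update_H
from lrcl.solver import (
    FitConfig,
    LRCLClassifier,
    ModelState,
    consensus_target,
    fit,
    objective,
    per_view_errors,
    predict_scores,
    ridge_prior,
    update_weights,
    update_Z,
)

from conftest import random_instance
from _oracles import simplex_weight_oracle, stacked_ls_Z_oracle


class TestRidgePrior:
    def test_identity_case(self):
        P = ridge_prior(np.eye(2), np.eye(2), ridge_lambda=1.0)
        np.testing.assert_allclose(P, 0.5 * np.eye(2), atol=1e-12)

    def test_exact_interpolation_at_zero(self, rng):
        X = rng.standard_normal((3, 3)) + np.eye(3)
        Y = encode_labels([0, 1, 2]).Y
        P = ridge_prior(X, Y, ridge_lambda=0.0)
        np.testing.assert_allclose(P, np.linalg.solve(X, Y), atol=1e-8)

    def test_matches_sklearn_ridge(self, rng):
        X = rng.standard_normal((20, 5))
        Y = encode_labels(rng.integers(0, 2, size=18).tolist() + [0, 1]).Y
        P = ridge_prior(X, Y, ridge_lambda=0.5)
        ref = Ridge(alpha=0.5, fit_intercept=False).fit(X, Y).coef_.T
        np.testing.assert_allclose(P, ref, atol=1e-10)

    def test_singular_without_ridge_rejected(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])  # rank 1
        Y = encode_labels([0, 1, 0]).Y
        with pytest.raises(np.linalg.LinAlgError, match="ridge_lambda"):
            ridge_prior(X, Y, ridge_lambda=0.0)


class TestConsensusTarget:
    def test_two_views(self, rng):
        X = [rng.standard_normal((6, 3)), rng.standard_normal((6, 4))]
        P = [rng.standard_normal((3, 2)), rng.standard_normal((4, 2))]
        np.testing.assert_allclose(consensus_target(X, P, 0), X[1] @ P[1])
        np.testing.assert_allclose(consensus_target(X, P, 1), X[0] @ P[0])

    def test_three_views_average(self, rng):
        X = [rng.standard_normal((5, d)) for d in (2, 3, 4)]
        P = [rng.standard_normal((d, 2)) for d in (2, 3, 4)]
        expected = (X[1] @ P[1] + X[2] @ P[2]) / 2.0
        np.testing.assert_allclose(consensus_target(X, P, 0), expected)

    def test_single_view_fit_disables_consistency(self, rng):
        X = rng.standard_normal((12, 3))
        labels = np.array([0, 1] * 6)
        with pytest.warns(UserWarning, match="beta = 0"):
            state, _ = fit([X], labels, FitConfig(beta=1.0, alpha=0.0, max_iter=5))
        assert np.all(state.C_targets[0] == 0)


class TestUpdateZ:
    def test_square_invertible_least_squares_limit(self, rng):
        X = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        Y = encode_labels([0, 1, 2]).Y
        Z = update_Z(X, Y, np.zeros_like(Y), np.zeros((3, 3)), 1.0, 0.0, 0.0, jitter=0.0)
        np.testing.assert_allclose(Z, np.linalg.solve(X, Y), atol=1e-8)

    def test_tall_matrix_matches_ols(self, rng):
        X = rng.standard_normal((25, 4))
        Y = encode_labels(rng.integers(0, 2, size=23).tolist() + [0, 1]).Y
        Z = update_Z(X, Y, np.zeros_like(Y), np.zeros((25, 25)), 1.0, 0.0, 0.0, jitter=0.0)
        ref, *_ = np.linalg.lstsq(X, Y, rcond=None)
        np.testing.assert_allclose(Z, ref, atol=1e-10)

    def test_jitter_as_ridge(self, rng):
        X = rng.standard_normal((15, 6))
        Y = encode_labels(rng.integers(0, 2, size=13).tolist() + [0, 1]).Y
        Z = update_Z(X, Y, np.zeros_like(Y), np.zeros((15, 15)), 1.0, 0.0, 0.0, jitter=0.7)
        ref = Ridge(alpha=0.7, fit_intercept=False).fit(X, Y).coef_.T
        np.testing.assert_allclose(Z, ref, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_stacked_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng, N=40, d=(8,), C=2, alpha=0.1, beta=0.5)
        X = inst["X"][0]
        Y = inst["Y"]
        C = inst["C"][0]
        L = inst["graphs"][0].L
        omega_k = 0.6
        Z = update_Z(X, Y, C, L, omega_k, 0.1, 0.5, jitter=0.0)
        Z_ref = stacked_ls_Z_oracle(X, Y, C, L, omega_k, 0.1, 0.5)
        np.testing.assert_allclose(Z, Z_ref, atol=1e-8)

    def test_block_objective_not_improvable(self, rng):
        # the closed form should beat small random perturbations of itself
        inst = random_instance(rng, N=20, d=(5, 4), C=2, alpha=0.3, beta=0.5)
        X, Y, C, L = inst["X"][0], inst["Y"], inst["C"][0], inst["graphs"][0].L
        w, a, b = 0.35, inst["alpha"], inst["beta"]

        def block_J(Z):
            M = X @ Z
            return (
                w * (np.sum((M - Y) ** 2) + b * np.sum((M - C) ** 2))
                + a * np.trace(Z.T @ X.T @ L @ X @ Z)
            )

        Z = update_Z(X, Y, C, L, w, a, b, jitter=0.0)
        base = block_J(Z)
        for _ in range(20):
            assert block_J(Z + 1e-3 * rng.standard_normal(Z.shape)) >= base - 1e-12


class TestUpdateWeights:
    def test_symmetry(self):
        np.testing.assert_allclose(update_weights([3.7, 3.7]), [0.5, 0.5])

    def test_log_three(self):
        np.testing.assert_allclose(update_weights([0.0, np.log(3)]), [0.75, 0.25], atol=1e-12)

    def test_huge_errors_no_underflow(self):
        w = update_weights([1e6, 1e6 + 1.0])
        assert np.all(np.isfinite(w)) and w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            update_weights([1.0, np.inf])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_simplex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.uniform(0, 5, size=int(rng.integers(2, 5)))
        np.testing.assert_allclose(update_weights(E), simplex_weight_oracle(E), atol=1e-8)


class TestObjective:
    def test_uniform_weights_zero_residuals(self):
        # two perfect views: J reduces to the entropy of uniform weights
        Y = encode_labels([0, 1]).Y
        X = [np.eye(2), np.eye(2)]
        graphs = [edge_weights(x, np.array([0, 1]), delta=1.0) for x in X]
        state = ModelState(
            Z=[Y.copy(), Y.copy()],
            omega=np.array([0.5, 0.5]),
            P=[Y.copy(), Y.copy()],
            C_targets=[np.zeros_like(Y), np.zeros_like(Y)],
            graphs=graphs,
            U=build_luxury_matrix(Y),
            H=np.zeros_like(Y),
        )
        J = objective(X, state, Y, alpha=0.0, beta=0.0)
        assert J == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_single_view_all_zero(self):
        Y = encode_labels([0, 1]).Y
        X = [np.eye(2)]
        graphs = [edge_weights(np.eye(2), np.array([0, 1]), delta=1.0)]
        state = ModelState(
            Z=[Y.copy()], omega=np.array([1.0]), P=[Y.copy()],
            C_targets=[np.zeros_like(Y)], graphs=graphs,
            U=build_luxury_matrix(Y), H=np.zeros_like(Y),
        )
        assert objective(X, state, Y, 0.0, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_lower_bound_minus_log_K(self, small_dataset):
        state, _ = fit(
            small_dataset.views, small_dataset.labels, FitConfig(max_iter=30)
        )
        K = small_dataset.n_views
        assert all(J >= -np.log(K) - 1e-12 for J in state.objective_trace)


class TestFit:
    def test_converges_with_monotone_trace(self, small_dataset):
        state, _ = fit(small_dataset.views, small_dataset.labels, FitConfig())
        assert state.converged and state.iteration <= 200
        diffs = np.diff(state.objective_trace)
        assert np.all(diffs <= 1e-9)

    def test_deterministic_repeats(self, small_dataset):
        cfg = FitConfig(seed=5)
        s1, _ = fit(small_dataset.views, small_dataset.labels, cfg)
        s2, _ = fit(small_dataset.views, small_dataset.labels, cfg)
        assert len(s1.objective_trace) == len(s2.objective_trace)
        np.testing.assert_array_equal(s1.omega, s2.omega)
        np.testing.assert_array_equal(s1.Z[0], s2.Z[0])

    def test_random_init_seeded(self, small_dataset):
        cfg = FitConfig(init="random", seed=3)
        s1, _ = fit(small_dataset.views, small_dataset.labels, cfg)
        s2, _ = fit(small_dataset.views, small_dataset.labels, cfg)
        np.testing.assert_array_equal(s1.omega, s2.omega)

    def test_constraints_hold_every_iteration(self, small_dataset):
        records = []

        def monitor(it, state):
            records.append((state.omega.copy(), state.H.copy()))

        state, lm = fit(
            small_dataset.views, small_dataset.labels, FitConfig(), monitor=monitor
        )
        U = state.U
        for omega, H in records:
            assert abs(omega.sum() - 1.0) <= 1e-12
            assert np.all(omega > 0)
            assert np.all(H >= 0)
            Yr = relax_labels(lm.Y, U, H)
            assert np.all(Yr[lm.Y == 1] >= 1.0) and np.all(Yr[lm.Y == 0] <= 0.0)

    def test_single_view_ridge_limit(self, rng):
        # alpha = beta = 0, H frozen at 0, jitter as the ridge penalty:
        # one view degenerates to a plain ridge classifier
        X = rng.standard_normal((30, 5))
        labels = np.array([0, 1] * 15)
        cfg = FitConfig(alpha=0.0, beta=0.0, jitter=0.8, learn_relaxation=False)
        state, lm = fit([X], labels, cfg)
        ref = Ridge(alpha=0.8, fit_intercept=False).fit(X, lm.Y).coef_.T
        np.testing.assert_allclose(state.Z[0], ref, atol=1e-10)
        assert state.converged and state.iteration <= 2

    def test_fixed_point_block_updates(self, small_dataset):
        cfg = FitConfig()
        state, lm = fit(small_dataset.views, small_dataset.labels, cfg)
        X_all = small_dataset.views
        Y = lm.Y
        J0 = objective(X_all, state, Y, cfg.alpha, cfg.beta)
        Yr = relax_labels(Y, state.U, state.H)
        # re-run each block once: J must not move by more than 1e-8
        Z_new = [
            update_Z(X, Yr, C, g.L, float(w), cfg.alpha, cfg.beta, cfg.jitter)
            for X, C, g, w in zip(X_all, state.C_targets, state.graphs, state.omega)
        ]
        state_z = dataclasses.replace(state, Z=Z_new)
        assert abs(objective(X_all, state_z, Y, cfg.alpha, cfg.beta) - J0) < 1e-8
        E = per_view_errors(X_all, state.Z, Yr, state.C_targets, cfg.beta)
        state_w = dataclasses.replace(state, omega=update_weights(E))
        assert abs(objective(X_all, state_w, Y, cfg.alpha, cfg.beta) - J0) < 1e-8
        fused = sum(w * (X @ Z) for w, X, Z in zip(state.omega, X_all, state.Z))
        state_h = dataclasses.replace(state, H=update_H(fused, Y, state.U))
        assert abs(objective(X_all, state_h, Y, cfg.alpha, cfg.beta) - J0) < 1e-8


class TestPredict:
    def test_identity_propagation(self, rng):
        Z = rng.standard_normal((4, 2))
        S = predict_scores([np.eye(4)], [Z], np.array([1.0]))
        np.testing.assert_array_equal(S, Z)

    def test_tie_breaks_to_lowest_index(self, small_dataset):
        clf = LRCLClassifier(max_iter=3).fit(
            small_dataset.views, small_dataset.labels
        )
        clf.state_.Z = [np.zeros_like(Z) for Z in clf.state_.Z]  # force all-tie scores
        pred = clf.predict(small_dataset.views)
        assert all(p == clf.classes_[0] for p in pred)

    def test_weighted_sum_linearity(self, rng):
        X = [rng.standard_normal((6, 3)), rng.standard_normal((6, 4))]
        Z = [rng.standard_normal((3, 2)), rng.standard_normal((4, 2))]
        omega = np.array([0.3, 0.7])
        S = predict_scores(X, Z, omega)
        expected = 0.3 * X[0] @ Z[0] + 0.7 * X[1] @ Z[1]
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_feature_mismatch_names_view(self, small_dataset, rng):
        clf = LRCLClassifier(max_iter=3).fit(small_dataset.views, small_dataset.labels)
        bad = [small_dataset.views[0], rng.standard_normal((5, 2))]
        with pytest.raises(ValueError, match="view 1"):
            clf.predict(bad)


class TestPersistence:
    def test_round_trip_reproduces_predictions_bitwise(self, small_dataset, tmp_path):
        clf = LRCLClassifier(max_iter=20).fit(small_dataset.views, small_dataset.labels)
        S1 = clf.predict_scores(small_dataset.views)
        clf.save(tmp_path / "model")
        clf2 = LRCLClassifier.load(tmp_path / "model")
        S2 = clf2.predict_scores(small_dataset.views)
        np.testing.assert_array_equal(S1, S2)
        np.testing.assert_array_equal(clf.state_.omega, clf2.state_.omega)
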