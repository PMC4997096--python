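"""Rank-constrained logistic regression and its ADMM solver."""

import warnings

import numpy as np
import pytest

from lowrankeeg.lowrank import (
    ADMMState,
    FitConfig,
    admm_fit,
    decision_function,
    load_model,
    logistic_objective,
    predict,
    rank_projection,
    residual_norms,
    save_model,
    theta_update,
)
from lowrankeeg.preprocess import CovFeature

from conftest import random_spd


def planted_covariances(rng, n=40, dim=5, gap=1.0, noise=0.05):
    """Covariance-like features separated along a planted rank-1 direction."""
    a = rng.standard_normal(dim)
    a /= np.linalg.norm(a)
    covs, labels = [], []
    for i in range(n):
        y = 1 if i % 2 == 0 else -1
        E = noise * rng.standard_normal((dim, dim))
        M = np.eye(dim) + y * gap * np.outer(a, a) + E @ E.T
        covs.append(CovFeature(matrix=0.5 * (M + M.T), label=y))
        labels.append(y)
    return covs, labels, a


class TestLogisticObjective:
    def test_zero_model_gives_n_log2(self, rng):
        covs, labels, _ = planted_covariances(rng, n=10)
        loss, gt, gb = logistic_objective(np.zeros((5, 5)), 0.0, covs, labels)
        assert loss == pytest.approx(10 * np.log(2), rel=1e-12)

    def test_saturated_bias_limit(self, rng):
        covs = [CovFeature(matrix=np.eye(3), label=+1)]
        loss, _, _ = logistic_objective(np.zeros((3, 3)), 50.0, covs, [+1])
        assert loss < 1e-20

    def test_gradient_matches_finite_differences(self, rng):
        covs, labels, _ = planted_covariances(rng, n=12, dim=3)
        theta = 0.3 * rng.standard_normal((3, 3))
        b = 0.2
        loss, gt, gb = logistic_objective(theta, b, covs, labels)
        h = 1e-6
        for idx in [(0, 0), (1, 2), (2, 1)]:
            tp, tm = theta.copy(), theta.copy()
            tp[idx] += h
            tm[idx] -= h
            num = (
                logistic_objective(tp, b, covs, labels)[0]
                - logistic_objective(tm, b, covs, labels)[0]
            ) / (2 * h)
            assert num == pytest.approx(gt[idx], rel=1e-5, abs=1e-10)
        num_b = (
            logistic_objective(theta, b + h, covs, labels)[0]
            - logistic_objective(theta, b - h, covs, labels)[0]
        ) / (2 * h)
        assert num_b == pytest.approx(gb, rel=1e-5, abs=1e-10)

    def test_bad_label_rejected(self, rng):
        covs = [CovFeature(matrix=np.eye(2), label=0)]
        with pytest.raises(ValueError, match="labels"):
            logistic_objective(np.zeros((2, 2)), 0.0, covs, [0])


class TestRankProjection:
    def test_rank1_idempotent(self, rng):
        M = np.outer(rng.standard_normal(4), rng.standard_normal(4))
        assert np.linalg.norm(rank_projection(M, 1) - M) <= 1e-10

    def test_full_rank_unchanged(self, rng):
        M = rng.standard_normal((4, 6))
        np.testing.assert_array_equal(rank_projection(M, 4), M)

    def test_eckart_young_error(self, rng):
        M = rng.standard_normal((5, 5))
        P = rank_projection(M, 2)
        s = np.linalg.svd(M, compute_uv=False)
        expected = np.sqrt(np.sum(s[2:] ** 2))
        assert np.linalg.norm(M - P) == pytest.approx(expected, rel=1e-10)


class TestThetaUpdate:
    def make_state(self, rng, dim=3, rho=1.0):
        xi = rng.standard_normal((dim, dim))
        ups = rng.standard_normal((dim, dim))
        return ADMMState(
            theta=np.zeros((dim, dim)),
            xi=xi,
            upsilon=ups,
            bias=0.0,
            rho=rho,
            iteration=0,
        )

    def test_penalty_dominated_limit(self, rng):
        covs, labels, _ = planted_covariances(rng, n=10, dim=3)
        from lowrankeeg.lowrank import _check_labels, _stack

        state = self.make_state(rng, rho=1e8)
        theta, b = theta_update(
            state, _stack(covs), _check_labels(labels), FitConfig(), 1e-10
        )
        assert np.linalg.norm(theta - (state.xi - state.upsilon)) <= 1e-3

    def test_empty_data_exact_minimizer(self, rng):
        state = self.make_state(rng, rho=2.0)
        theta, b = theta_update(
            state, np.empty((0, 9)), np.empty(0), FitConfig(), 1e-12
        )
        np.testing.assert_allclose(
            theta, state.xi - state.upsilon, atol=1e-9
        )

    def test_local_optimality_against_random_probes(self, rng):
        covs, labels, _ = planted_covariances(rng, n=16, dim=3)
        from lowrankeeg.lowrank import _check_labels, _stack

        D, y = _stack(covs), _check_labels(labels)
        state = self.make_state(rng, rho=1.0)
        theta, b = theta_update(state, D, y, FitConfig(), 1e-10)

        def objective(t, bb):
            loss, _, _ = logistic_objective(t, bb, covs, labels)
            return loss + 0.5 * np.linalg.norm(
                t - state.xi + state.upsilon
            ) ** 2

        base = objective(theta, b)
        for _ in range(200):
            dt = 1e-3 * rng.standard_normal((3, 3))
            db = 1e-3 * rng.standard_normal()
            assert objective(theta + dt, b + db) >= base - 1e-9


class TestADMMFit:
    def test_separable_data_reaches_zero_training_error(self, rng):
        covs, labels, _ = planted_covariances(rng, gap=3.0, noise=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = admm_fit(covs, labels, FitConfig(rank=1, max_iter=200))
        _, pred = predict(model, covs)
        assert np.mean(pred != np.array(labels)) == 0.0

    def test_single_class_rejected(self, rng):
        covs = [CovFeature(matrix=np.eye(3), label=+1)] * 4
        with pytest.raises(ValueError, match="both classes"):
            admm_fit(covs, [+1] * 4, FitConfig(rank=1))

    def test_full_rank_matches_unconstrained_logistic(self, rng):
        # overlapping classes so the unconstrained minimizer is finite
        covs, labels, _ = planted_covariances(
            rng, n=60, dim=3, gap=0.3, noise=0.6
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = admm_fit(
                covs, labels, FitConfig(rank=3, max_iter=400, rho=1.0)
            )
        loss_admm, _, _ = logistic_objective(
            model.theta, model.bias, covs, labels
        )

        # independent oracle: direct minimization of the same loss
        from scipy import optimize

        def fun(x):
            loss, gt, gb = logistic_objective(
                x[:-1].reshape(3, 3), x[-1], covs, labels
            )
            return loss, np.concatenate([gt.ravel(), [gb]])

        res = optimize.minimize(
            fun, np.zeros(10), jac=True, method="L-BFGS-B",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        assert loss_admm <= res.fun * 1.01 + 1e-8

    def test_feasibility_of_returned_theta(self, rng):
        covs, labels, _ = planted_covariances(rng, n=30, dim=5, noise=0.4)
        for c in (1, 2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                model = admm_fit(covs, labels, FitConfig(rank=c, max_iter=150))
            s = np.linalg.svd(model.theta, compute_uv=False)
            assert np.all(s[c:] <= 1e-8 * s[0])

    def test_training_loss_non_increasing_in_rank(self, rng):
        covs, labels, _ = planted_covariances(
            rng, n=60, dim=8, gap=0.8, noise=0.3
        )
        losses = []
        for c in (1, 2, 4, 8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                model = admm_fit(
                    covs,
                    labels,
                    FitConfig(rank=c, max_iter=300, whiten=True,
                              nuclear_weight=0.1, rho=2.0),
                )
            loss, _, _ = logistic_objective(
                model.theta, model.bias, covs, labels
            )
            losses.append(loss)
        for lo, hi in zip(losses[1:], losses[:-1]):
            assert lo <= hi * 1.05 + 1e-6

    def test_fit_is_deterministic(self, rng):
        covs, labels, _ = planted_covariances(rng, n=20, dim=4, noise=0.3)
        cfg = FitConfig(rank=2, max_iter=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m1 = admm_fit(covs, labels, cfg)
            m2 = admm_fit(covs, labels, cfg)
        np.testing.assert_array_equal(m1.theta, m2.theta)
        assert m1.bias == m2.bias

    def test_symmetric_singular_vectors_on_symmetric_features(self, rng):
        # with symmetric covariance features the fitted coefficient matrix
        # is symmetric, so left/right singular vectors agree up to sign
        covs, labels, _ = planted_covariances(rng, n=40, dim=5, noise=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = admm_fit(covs, labels, FitConfig(rank=2, max_iter=200))
        U, s, Vt = np.linalg.svd(model.theta)
        for i in range(2):
            assert abs(U[:, i] @ Vt[i]) > 0.99


class TestReformulation:
    def test_trace_form_equals_filter_sum(self, rng):
        # <Theta, X X^T> with Theta = sum_j theta_j w_j w_j^T equals
        # sum_j theta_j ||w_j^T X||^2
        for _ in range(20):
            C, J, T = 6, 3, 50
            W = rng.standard_normal((C, J))
            theta_j = rng.standard_normal(J)
            X = rng.standard_normal((C, T))
            Theta = sum(
                theta_j[j] * np.outer(W[:, j], W[:, j]) for j in range(J)
            )
            lhs = np.sum(Theta * (X @ X.T))
            rhs = sum(
                theta_j[j] * np.sum((W[:, j] @ X) ** 2) for j in range(J)
            )
            scale = sum(abs(theta_j[j]) * np.sum((W[:, j] @ X) ** 2)
                        for j in range(J))
            assert abs(lhs - rhs) <= 1e-10 * scale

    def test_multiband_objective_decomposes_over_blocks(self, rng):
        # logistic loss on block-diagonal features equals the loss of a
        # single problem whose inner products are per-band sums
        from scipy.linalg import block_diag

        n, C, K = 8, 3, 2
        thetas = [rng.standard_normal((C, C)) for _ in range(K)]
        Theta = block_diag(*thetas)
        covs, per_band = [], []
        labels = [1 if i % 2 == 0 else -1 for i in range(n)]
        for i in range(n):
            blocks = [random_spd(rng, C) for _ in range(K)]
            covs.append(
                CovFeature(matrix=block_diag(*blocks), label=labels[i])
            )
            per_band.append(blocks)
        loss, _, _ = logistic_objective(Theta, 0.1, covs, labels)
        manual = 0.0
        for i in range(n):
            f = 0.1 + sum(
                np.sum(thetas[k] * per_band[i][k]) for k in range(K)
            )
            manual += np.log1p(np.exp(-labels[i] * f))
        assert loss == pytest.approx(manual, rel=1e-10)


class TestPredict:
    def test_zero_model_gives_half(self):
        from lowrankeeg.lowrank import LowRankModel

        model = LowRankModel(theta=np.zeros((3, 3)), bias=0.0, rank_constraint=1)
        proba, label = predict(model, CovFeature(matrix=np.eye(3)))
        assert proba == 0.5
        assert label == +1  # ties go to +1

    def test_saturated_bias(self):
        from lowrankeeg.lowrank import LowRankModel

        model = LowRankModel(theta=np.zeros((2, 2)), bias=10.0, rank_constraint=1)
        proba, _ = predict(model, CovFeature(matrix=np.eye(2)))
        assert proba > 0.9999

    def test_matches_elementwise_sum_oracle(self, rng):
        from lowrankeeg.lowrank import LowRankModel

        theta = rng.standard_normal((4, 4))
        sigma = random_spd(rng, 4)
        model = LowRankModel(theta=theta, bias=-0.7, rank_constraint=4)
        f = decision_function(model, CovFeature(matrix=sigma))
        expected = -0.7 + np.sum(theta * sigma)
        assert f[0] == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_named(self, rng):
        from lowrankeeg.lowrank import LowRankModel

        model = LowRankModel(theta=np.zeros((3, 3)), bias=0.0, rank_constraint=1)
        with pytest.raises(ValueError, match="does not match"):
            predict(model, CovFeature(matrix=np.eye(4)))


class TestResiduals:
    def test_primal_zero_when_consensus(self, rng):
        M = rng.standard_normal((3, 3))
        state = ADMMState(
            theta=M, xi=M.copy(), upsilon=np.zeros((3, 3)),
            bias=0.0, rho=2.0, iteration=1, dual_norm=0.0,
        )
        primal, _ = residual_norms(state)
        assert primal == 0.0

    def test_dual_zero_when_xi_static(self, rng):
        M = rng.standard_normal((3, 3))
        state = ADMMState(
            theta=M, xi=M, upsilon=M, bias=0.0, rho=2.0, iteration=1
        )
        _, dual = residual_norms(state, xi_prev=M.copy())
        assert dual == 0.0

    def test_matches_hand_computed_norms(self, rng):
        theta = rng.standard_normal((3, 3))
        xi = rng.standard_normal((3, 3))
        xi_prev = rng.standard_normal((3, 3))
        state = ADMMState(
            theta=theta, xi=xi, upsilon=np.zeros((3, 3)),
            bias=0.0, rho=3.0, iteration=2,
        )
        primal, dual = residual_norms(state, xi_prev=xi_prev)
        assert primal == pytest.approx(np.sqrt(np.sum((theta - xi) ** 2)))
        assert dual == pytest.approx(3.0 * np.sqrt(np.sum((xi - xi_prev) ** 2)))


class TestSerialization:
    def test_round_trip_exact(self, rng, tmp_path):
        covs, labels, _ = planted_covariances(rng, n=20, dim=3, noise=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = admm_fit(covs, labels, FitConfig(rank=2, max_iter=50))
        path = str(tmp_path / "model.json")
        save_model(path, model)
        loaded = load_model(path)
        np.testing.assert_array_equal(model.theta, loaded.theta)
        assert model.bias == loaded.bias
        assert model.rank_constraint == loaded.rank_constraint
        np.testing.assert_array_equal(
            decision_function(model, covs), decision_function(loaded, covs)
        )
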