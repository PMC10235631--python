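import numpy as np
import pandas as pd
import pytest

from osteotex.errors import SchemaError
from osteotex.nca_select import (
    FEATURE_NAMES,
    _objective_and_grad,
    ballot_rank,
    cv_select_lambda,
    lambda_grid,
    ncfs_fit,
)


def brute_force_objective(w, X, y, lam):
    """Literal softmax/objective evaluation with python loops."""
    n, d = X.shape
    f = 0.0
    p_list = []
    for i in range(n):
        ks = {}
        for l in range(n):
            if l == i:
                continue
            dist = sum((w[j] ** 2) * abs(X[i, j] - X[l, j]) for j in range(d))
            ks[l] = np.exp(-dist)
        z = sum(ks.values())
        p_i = sum(k for l, k in ks.items() if y[l] == y[i]) / z
        p_list.append(p_i)
    f = sum(p_list) - lam * sum(wj**2 for wj in w)
    return f, p_list


def _zscore(X):
    return (X - X.mean(0)) / X.std(0)


def make_synthetic(rng, n=60, d=11, informative=(0, 3), gap=2.0):
    X = rng.standard_normal((n, d))
    y = np.repeat([0, 1], n // 2)
    for j in informative:
        X[:, j] += gap * y
    return X, y


class TestNCFSFit:
    def test_softmax_matches_brute_force_on_5_points(self, rng):
        X = rng.standard_normal((5, 1))
        y = np.array([0, 1, 0, 1, 0])
        w = np.array([0.8])
        f_fast, _, p_mean = _objective_and_grad(
            w,
            np.ascontiguousarray(np.abs(X[:, None, :] - X[None, :, :])),
            _same_matrix(y),
            0.0,
        )
        f_slow, p_list = brute_force_objective(w, X, y, 0.0)
        assert f_fast == pytest.approx(f_slow, abs=1e-12)
        assert p_mean == pytest.approx(np.mean(p_list), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        X = _zscore(rng.standard_normal((12, 4)))
        y = np.array([0, 1] * 6)
        A = np.ascontiguousarray(np.abs(X[:, None, :] - X[None, :, :]))
        S = _same_matrix(y)
        w = np.abs(rng.standard_normal(4)) + 0.1
        f0, grad, _ = _objective_and_grad(w, A, S, 0.05)
        eps = 1e-7
        for j in range(4):
            wp = w.copy()
            wp[j] += eps
            fp, _, _ = _objective_and_grad(wp, A, S, 0.05)
            assert grad[j] == pytest.approx((fp - f0) / eps, abs=1e-4)

    def test_huge_lambda_kills_weights(self, rng):
        X, y = make_synthetic(rng, n=50, d=6, informative=(0,))
        fit = ncfs_fit(_zscore(X), y, lam=1e3)
        assert np.all(fit.weights < 1e-3)
        # with zero weights the soft-NN probability is the class-prior rate
        n_same = 24  # 25 per class, minus self
        assert fit.loss == pytest.approx(1 - n_same / 49, abs=1e-3)

    def test_informative_feature_gets_largest_weight(self):
        hits = 0
        for seed in range(100, 110):
            rng = np.random.default_rng(seed)
            X, y = make_synthetic(rng, n=50, d=6, informative=(0,), gap=6.0)
            fit = ncfs_fit(_zscore(X), y, lam=1.0 / 50)
            if np.argmax(fit.weights) == 0:
                hits += 1
        assert hits == 10

    def test_objective_nondecreasing_over_iterations(self, rng):
        X, y = make_synthetic(rng, n=30, d=5)
        fit, trace = ncfs_fit(_zscore(X), y, lam=0.01, return_trace=True)
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_weights_nonnegative(self, rng):
        X, y = make_synthetic(rng, n=40, d=8)
        fit = ncfs_fit(_zscore(X), y, lam=0.02)
        assert np.all(fit.weights >= 0)
        assert 0.0 <= fit.loss <= 1.0


class TestCVSelectLambda:
    def test_deterministic(self, rng):
        X, y = make_synthetic(rng)
        lam1, fit1 = cv_select_lambda((X, y), seed=42)
        lam2, fit2 = cv_select_lambda((X, y), seed=42)
        assert lam1 == lam2
        np.testing.assert_array_equal(fit1.weights, fit2.weights)

    def test_grid_definition(self):
        grid = lambda_grid(60)
        assert grid.size == 20
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(2.0 / 60)

    def test_pure_noise_loss_near_half(self):
        curves = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((60, 11))
            y = np.repeat([0, 1], 30)
            _, _, losses = cv_select_lambda((X, y), seed=seed, return_curve=True)
            curves.append(losses)
        mean_curve = np.mean(curves, axis=0)
        se = 0.5 / np.sqrt(20 * 60)  # 20 cohorts x 60 held-out labels
        assert np.all(np.abs(mean_curve - 0.5) <= 3 * se)


class TestBallotRank:
    def test_score_conservation(self, rng):
        X, y = make_synthetic(rng)
        result = ballot_rank((X, y), n_rounds=10, seed=5, keep_best=5)
        assert result.scores.sum() == 5 * 21

    def test_identical_features_tie_break_deterministic(self, rng):
        col = rng.standard_normal(40)
        X = np.tile(col[:, None], (1, 11))
        y = np.repeat([0, 1], 20)
        result = ballot_rank((X, y), n_rounds=6, seed=1, keep_best=3)
        # every round identical weights -> canonical order wins every ballot
        np.testing.assert_array_equal(
            result.scores, [6 * 3, 5 * 3, 4 * 3, 3 * 3, 2 * 3, 1 * 3, 0, 0, 0, 0, 0]
        )

    def test_feature_table_schema(self, rng):
        X, y = make_synthetic(rng, n=30)
        table = pd.DataFrame(X, columns=FEATURE_NAMES)
        table["label"] = y
        result = ballot_rank(table, n_rounds=4, seed=2, keep_best=2)
        assert set(result.selected) <= set(FEATURE_NAMES)
        assert result.scores.sum() == 2 * 21

    def test_missing_column_rejected(self, rng):
        table = pd.DataFrame(np.zeros((20, 3)), columns=["a", "b", "c"])
        table["label"] = [0, 1] * 10
        with pytest.raises(SchemaError):
            ballot_rank(table, n_rounds=2, seed=0, keep_best=1)

    def test_whole_pipeline_deterministic(self, rng):
        X, y = make_synthetic(rng, n=40)
        r1 = ballot_rank((X, y), n_rounds=6, seed=9, keep_best=3)
        r2 = ballot_rank((X, y), n_rounds=6, seed=9, keep_best=3)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.ranking == r2.ranking


def _same_matrix(y):
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    return same
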