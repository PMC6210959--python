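"""ELM core: activations, random layer, least-squares fit, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elmbloom.elm import (
    ELMModel,
    Scaler,
    activation,
    fit_output_weights,
    hidden_matrix,
    init_hidden,
    load_model,
    predict,
    save_model,
    train_elm,
)
from elmbloom.evaluation import rmse
from elmbloom.exceptions import ConfigurationError, NumericError

from conftest import make_supervised


class TestActivation:
    @pytest.mark.parametrize(
        "kind,w,b,x,expected",
        [
            ("sigmoid", [1.0, 1.0], -2.0, [1.0, 1.0], 0.5),   # w·x+b = 0
            ("sine", [1.0, 1.0], -2.0, [1.0, 1.0], 0.0),
            ("rbf", [0.3, -0.4], 0.7, [0.3, -0.4], 1.0),      # x = w
            ("sigmoid", [2.0], 1.0, [1.0], 1 / (1 + np.exp(-3.0))),
            ("sine", [2.0], 1.0, [0.5], np.sin(2.0)),
            ("rbf", [0.0], 2.0, [1.0], np.exp(-4.0)),
        ],
    )
    def test_scalar_values(self, kind, w, b, x, expected):
        assert activation(kind, np.array(w), b, np.array(x)) == pytest.approx(expected)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            activation("relu", np.ones(2), 0.0, np.ones(2))


class TestInitHidden:
    def test_deterministic_under_seed(self):
        a = init_hidden(5, 3, seed=42)
        b = init_hidden(5, 3, seed=42)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b, b.b)

    def test_shapes(self):
        layer = init_hidden(3, 2, seed=0)
        assert layer.W.shape == (3, 2) and layer.b.shape == (3,)

    def test_rbf_biases_strictly_positive(self):
        layer = init_hidden(50, 4, activation="rbf", seed=0)
        assert layer.b.min() > 0

    def test_layers_nested_across_L(self):
        small = init_hidden(4, 3, seed=9)
        big = init_hidden(7, 3, seed=9)
        np.testing.assert_array_equal(big.W[:4], small.W)
        np.testing.assert_array_equal(big.b[:4], small.b)

    def test_bounds_follow_weight_scale(self):
        auto = init_hidden(200, 4, seed=1)
        assert np.abs(auto.W).max() <= 1 / np.sqrt(4)
        plain = init_hidden(200, 4, seed=1, weight_scale=1.0)
        assert np.abs(plain.W).max() <= 1.0
        assert np.abs(plain.W).max() > 1 / np.sqrt(4)
        assert np.abs(plain.b).max() <= 1.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            init_hidden(0, 3)
        with pytest.raises(ValueError):
            init_hidden(3, 0)


class TestHiddenMatrix:
    def test_zero_weights_sigmoid_gives_half(self):
        layer = init_hidden(4, 2, seed=0)
        object.__setattr__(layer, "W", np.zeros((4, 2)))
        object.__setattr__(layer, "b", np.zeros(4))
        H = hidden_matrix(layer, np.random.default_rng(0).normal(size=(6, 2)))
        np.testing.assert_allclose(H, 0.5)

    def test_single_row_shape(self):
        layer = init_hidden(5, 3, seed=1)
        assert hidden_matrix(layer, np.zeros((1, 3))).shape == (1, 5)

    @pytest.mark.parametrize("kind", ["sigmoid", "rbf", "sine"])
    def test_matches_entrywise_scalar_calls(self, kind):
        layer = init_hidden(3, 2, activation=kind, seed=5)
        X = np.random.default_rng(2).normal(size=(4, 2))
        H = hidden_matrix(layer, X)
        loops = np.array(
            [
                [activation(kind, layer.W[j], layer.b[j], X[i]) for j in range(3)]
                for i in range(4)
            ]
        )
        np.testing.assert_allclose(H, loops, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        layer = init_hidden(3, 2, seed=0)
        with pytest.raises(ValueError):
            hidden_matrix(layer, np.zeros((4, 5)))


class TestFitOutputWeights:
    def test_orthonormal_columns_reduce_to_projection(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(10, 4)))
        T = rng.normal(size=10)
        np.testing.assert_allclose(fit_output_weights(Q, T), Q.T @ T, atol=1e-10)

    def test_square_nonsingular_solves_exactly(self):
        rng = np.random.default_rng(4)
        H = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        T = rng.normal(size=6)
        beta = fit_output_weights(H, T)
        assert np.linalg.norm(H @ beta - T) <= 1e-8 * np.linalg.norm(T)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        H = rng.normal(size=(12, 4))
        T = rng.normal(size=12)
        oracle = np.linalg.solve(H.T @ H, H.T @ T)
        np.testing.assert_allclose(fit_output_weights(H, T), oracle, atol=1e-8)

    def test_rank_deficient_returns_min_norm_solution(self):
        H = np.ones((8, 3))  # rank 1
        T = np.full(8, 6.0)
        beta = fit_output_weights(H, T)
        np.testing.assert_allclose(H @ beta, T, atol=1e-10)
        np.testing.assert_allclose(beta, np.full(3, 2.0), atol=1e-10)  # min-norm

    def test_non_finite_rejected(self):
        with pytest.raises(NumericError):
            fit_output_weights(np.array([[1.0, np.inf]]), np.array([1.0]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_residual_orthogonal_to_columns(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(3, 30)), int(rng.integers(1, 12))
        H = rng.normal(size=(n, L))
        T = rng.normal(size=n)
        beta = fit_output_weights(H, T)
        resid = H @ beta - T
        assert np.abs(H.T @ resid).max() < 1e-6 * max(np.linalg.norm(T), 1e-12)


class TestTrainPredict:
    def test_interpolates_when_L_equals_N(self):
        sset = make_supervised(10, seed=2, fn=lambda X: np.sin(X).sum(axis=1))
        model = train_elm(sset, L=10, seed=0)
        assert rmse(sset.T, predict(model, sset.X)) < 1e-6

    def test_deterministic_given_seed(self):
        sset = make_supervised(20, seed=3)
        m1 = train_elm(sset, 8, seed=11)
        m2 = train_elm(sset, 8, seed=11)
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_beta_recovery_from_known_generator(self):
        gen = init_hidden(5, 3, seed=21)
        beta_true = np.random.default_rng(6).normal(0, 2, 5)
        X = np.random.default_rng(7).uniform(-2, 2, size=(100, 3))
        T = hidden_matrix(gen, X) @ beta_true
        beta_hat = fit_output_weights(hidden_matrix(gen, X), T)
        np.testing.assert_allclose(beta_hat, beta_true, atol=1e-6)

    def test_zero_beta_predicts_zero(self):
        sset = make_supervised(10)
        model = train_elm(sset, 4, seed=0)
        zeroed = ELMModel(hidden=model.hidden, beta=np.zeros(4),
                          scaler=model.scaler, d=model.d)
        np.testing.assert_allclose(predict(zeroed, sset.X), 0.0)

    def test_saturated_sigmoid_prediction_approaches_beta(self):
        layer = init_hidden(1, 1, seed=0)
        object.__setattr__(layer, "W", np.array([[1.0]]))
        object.__setattr__(layer, "b", np.array([0.0]))
        model = ELMModel(hidden=layer, beta=np.array([3.7]),
                         scaler=Scaler.identity(1), d=1)
        assert predict(model, np.array([[50.0]]))[0] == pytest.approx(3.7, abs=1e-9)

    def test_hand_evaluated_two_node_model(self):
        layer = init_hidden(2, 1, seed=0)
        object.__setattr__(layer, "W", np.array([[1.0], [-1.0]]))
        object.__setattr__(layer, "b", np.array([0.0, 0.5]))
        model = ELMModel(hidden=layer, beta=np.array([2.0, -1.0]),
                         scaler=Scaler.identity(1), d=1)
        x = np.array([[0.3], [0.0], [-1.2]])
        expected = 2.0 / (1 + np.exp(-x[:, 0])) - 1.0 / (1 + np.exp(-(-x[:, 0] + 0.5)))
        np.testing.assert_allclose(predict(model, x), expected, atol=1e-12)

    def test_training_rmse_non_increasing_in_L(self):
        # nested per-node seeding makes mean train RMSE monotone in capacity
        sset = make_supervised(40, seed=8, fn=lambda X: np.cos(X).prod(axis=1))
        means = []
        for L in range(1, 25):
            vals = [
                rmse(sset.T, predict(train_elm(sset, L, seed=s), sset.X))
                for s in range(20)
            ]
            means.append(np.mean(vals))
        diffs = np.diff(means)
        assert (diffs <= 1e-9).all()

    def test_degenerate_zero_layer_fits_constant(self):
        # W=0, b=0 gives a constant hidden column; the fit is the SSE-minimising constant
        for kind in ("sigmoid", "sine"):
            sset = make_supervised(15, seed=9)
            model = train_elm(sset, 3, activation=kind, seed=0)
            object.__setattr__(model.hidden, "W", np.zeros((3, sset.d)))
            object.__setattr__(model.hidden, "b", np.zeros(3))
            beta = fit_output_weights(hidden_matrix(model.hidden, sset.X), sset.T)
            refit = ELMModel(hidden=model.hidden, beta=beta,
                             scaler=Scaler.identity(sset.d), d=sset.d)
            yhat = predict(refit, sset.X)
            if kind == "sigmoid":
                np.testing.assert_allclose(yhat, sset.T.mean(), atol=1e-8)
            else:  # sine of zero is the zero column: only the zero constant fits
                np.testing.assert_allclose(yhat, 0.0, atol=1e-12)

    def test_perturbing_beta_never_reduces_training_sse(self):
        sset = make_supervised(25, seed=10, fn=lambda X: X[:, 0] ** 2)
        model = train_elm(sset, 6, seed=1)
        H = hidden_matrix(model.hidden, model.scaler.transform(sset.X))
        sse0 = np.sum((H @ model.beta - sset.T) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            delta = rng.normal(0, 0.1, size=6)
            sse = np.sum((H @ (model.beta + delta) - sset.T) ** 2)
            assert sse >= sse0 - 1e-9

    def test_serialization_round_trip_exact(self, tmp_path):
        sset = make_supervised(12, seed=4)
        model = train_elm(sset, 5, activation="rbf", seed=2)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.beta, model.beta)
        np.testing.assert_array_equal(back.hidden.W, model.hidden.W)
        np.testing.assert_array_equal(back.scaler.mean, model.scaler.mean)
        np.testing.assert_array_equal(
            predict(back, sset.X), predict(model, sset.X)
        )
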