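"""Comparison models: multiple linear regression, a backpropagation neural
network, and a Takagi–Sugeno neuro-fuzzy system (ANFIS) with fuzzy c-means
rule induction.

These are the reference methods the ELM is benchmarked against.  The neural
network is a single sigmoid hidden layer with a linear output, trained by
full-batch gradient descent on the sum-of-squares error (learning rate 0.001,
1000 epochs by default).  The ANFIS places one Gaussian fuzzy rule per
fuzzy c-means cluster; its first-order consequents are fitted in one pass by
least squares on the rule-weighted design matrix.  An optional hybrid
learning loop alternates that least-squares forward pass with a gradient
backward pass on the membership centres and spreads — used here to exhibit
the overfitting behaviour of antecedent tuning on small noisy datasets.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data import SupervisedSet
from .elm import Scaler
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    NumericError,
    OverfittingGuardError,
)

__all__ = [
    "LinearModel", "NNModel", "ANFISModel",
    "fit_linear_regression", "train_nn_bp", "fcm_cluster",
    "build_anfis_fcm", "train_anfis_hybrid", "predict_baseline",
]


# ---------------------------------------------------------------- linear ----

@dataclasses.dataclass(frozen=True)
class LinearModel:
    """Ordinary least squares with intercept."""

    coefficients: np.ndarray
    intercept: float


def fit_linear_regression(train: SupervisedSet | tuple) -> LinearModel:
    """Fit multiple linear regression by least squares.

    A rank-deficient design triggers a warning and falls back to the
    minimum-norm (pseudoinverse) solution.
    """
    X, y = _xy(train)
    n, d = X.shape
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < d + 1:
        warnings.warn("rank-deficient design; using minimum-norm solution", stacklevel=2)
    return LinearModel(coefficients=coef[1:], intercept=float(coef[0]))


# ------------------------------------------------------------------- NN -----

@dataclasses.dataclass
class NNModel:
    """Single-hidden-layer sigmoid network with linear output, trained by
    full-batch backpropagation.  Inputs and target are standardised
    internally on the training data; predictions are returned on the
    original scale."""

    W1: np.ndarray        # hidden_nodes × d
    b1: np.ndarray
    w2: np.ndarray        # hidden_nodes
    b2: float
    hidden_nodes: int
    learning_rate: float
    epochs: int
    seed: int
    loss_curve: np.ndarray  # per-epoch training RMSE, original target scale
    x_scaler: Scaler = None  # type: ignore[assignment]
    y_mean: float = 0.0
    y_scale: float = 1.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def train_nn_bp(
    train: SupervisedSet | tuple,
    hidden_nodes: int,
    learning_rate: float = 0.001,
    epochs: int = 1000,
    seed: int = 0,
) -> NNModel:
    """Train the backpropagation baseline.

    Full-batch gradient descent on E = ½·Σ(ŷ−t)²; the per-epoch training
    RMSE (original scale) is recorded after each update.  Divergence
    (non-finite loss) aborts with a diagnostic.
    """
    if hidden_nodes < 1:
        raise ValueError("hidden_nodes must be >= 1")
    X, y = _xy(train)
    x_scaler = Scaler.fit(X)
    Xs = x_scaler.transform(X)
    y_mean, y_scale = float(y.mean()), float(y.std()) or 1.0
    ys = (y - y_mean) / y_scale
    d = Xs.shape[1]

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1, 1, size=(hidden_nodes, d)) / np.sqrt(d)
    b1 = rng.uniform(-1, 1, size=hidden_nodes)
    w2 = rng.uniform(-1, 1, size=hidden_nodes) / np.sqrt(hidden_nodes)
    b2 = 0.0

    curve = np.empty(epochs)
    for epoch in range(epochs):
        A = _sigmoid(Xs @ W1.T + b1)          # N × h
        yhat = A @ w2 + b2
        err = yhat - ys                        # N
        # backprop through the linear output and sigmoid hidden layer
        g_w2 = A.T @ err
        g_b2 = err.sum()
        delta = np.outer(err, w2) * A * (1.0 - A)   # N × h
        g_W1 = delta.T @ Xs
        g_b1 = delta.sum(axis=0)
        W1 -= learning_rate * g_W1
        b1 -= learning_rate * g_b1
        w2 -= learning_rate * g_w2
        b2 -= learning_rate * g_b2

        A = _sigmoid(Xs @ W1.T + b1)
        resid = (A @ w2 + b2 - ys) * y_scale
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        if not np.isfinite(rmse):
            raise NumericError(f"backpropagation diverged at epoch {epoch}")
        curve[epoch] = rmse

    return NNModel(
        W1=W1, b1=b1, w2=w2, b2=float(b2),
        hidden_nodes=hidden_nodes, learning_rate=learning_rate,
        epochs=epochs, seed=seed, loss_curve=curve,
        x_scaler=x_scaler, y_mean=y_mean, y_scale=y_scale,
    )


# ------------------------------------------------------------------ FCM -----

def fcm_cluster(
    X: np.ndarray,
    r: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means clustering (alternating optimisation).

    Minimises J = Σ_i Σ_k u_ik^m ‖x_i − c_k‖² subject to row-stochastic
    memberships.  Returns ``(centers, memberships)`` with centers r×d and
    memberships N×r.  The objective is non-increasing across iterations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if r < 2:
        raise ValueError("fcm_cluster requires r >= 2")
    if n < r:
        raise ValueError(f"need at least r={r} points, got {n}")
    if np.allclose(X, X[0]):
        raise DegenerateInputError("all points identical; clusters are undefined")
    m = float(fuzzifier)
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")

    rng = np.random.default_rng(seed)
    U = rng.uniform(size=(n, r))
    U /= U.sum(axis=1, keepdims=True)
    prev = np.inf
    for _ in range(max_iter):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        # crisp assignment when a point coincides with a centre
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            inv = np.where(zero, np.inf, d2) ** (-1.0 / (m - 1))
        U_soft = inv / np.maximum(inv.sum(axis=1, keepdims=True), 1e-300)
        U = np.where(
            zero.any(axis=1, keepdims=True),
            zero / np.maximum(zero.sum(axis=1, keepdims=True), 1),
            U_soft,
        )
        obj = float(((U ** m) * d2).sum())
        if prev - obj < tol:
            break
        prev = obj
    return centers, U


def fcm_objective(X: np.ndarray, centers: np.ndarray, U: np.ndarray, fuzzifier: float = 2.0) -> float:
    """Evaluate the fuzzy c-means objective at a given solution."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = ((X[:, None, :] - np.atleast_2d(centers)[None, :, :]) ** 2).sum(axis=2)
    return float(((np.asarray(U) ** fuzzifier) * d2).sum())


# ---------------------------------------------------------------- ANFIS -----

@dataclasses.dataclass
class ANFISModel:
    """First-order Takagi–Sugeno system with Gaussian antecedents.

    Rule k fires with strength w_k(x) = Π_j exp(−(x_j−c_kj)²/(2σ_kj²));
    the prediction is Σ_k w̄_k(x)·(a_k0 + a_k·x) with normalised strengths
    w̄_k = w_k/Σw.  Centres come from fuzzy c-means; spreads are
    membership-weighted per-feature standard deviations.

    Internally the model lives in standardised feature space (``x_scaler``
    learned on the training rows): membership geometry and the hybrid
    backward pass are then well-conditioned regardless of raw units.
    Predictions accept and return raw-scale values.
    """

    r: int
    centers: np.ndarray      # r × d, standardised space
    spreads: np.ndarray      # r × d, > 0, standardised space
    consequents: np.ndarray  # r × (d+1), column 0 = intercept
    x_scaler: Scaler = None  # type: ignore[assignment]
    trained_epochs: int = 0


def _firing(model_or_cs, X: np.ndarray) -> np.ndarray:
    """Normalised rule firing strengths, N × r (rows sum to 1)."""
    if isinstance(model_or_cs, ANFISModel):
        centers, spreads = model_or_cs.centers, model_or_cs.spreads
    else:
        centers, spreads = model_or_cs
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = (X[:, None, :] - centers[None, :, :]) / spreads[None, :, :]
    logw = -0.5 * (z ** 2).sum(axis=2)            # N × r
    logw -= logw.max(axis=1, keepdims=True)       # stabilise the exponent
    w = np.exp(logw)
    total = w.sum(axis=1, keepdims=True)
    return np.where(total > 0, w / total, 1.0 / w.shape[1])


def _anfis_design(wbar: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Rule-weighted design matrix, N × r(d+1)."""
    n, d = X.shape
    r = wbar.shape[1]
    A1 = np.concatenate([np.ones((n, 1)), X], axis=1)   # N × (d+1)
    return (wbar[:, :, None] * A1[:, None, :]).reshape(n, r * (d + 1))


def build_anfis_fcm(
    train: SupervisedSet | tuple,
    r: int,
    fuzzifier: float = 2.0,
    seed: int = 0,
    spread_floor_frac: float = 1e-3,
    spread_scale: float = 2.0,
) -> ANFISModel:
    """One-pass ANFIS: fuzzy c-means antecedents, least-squares consequents.

    ``spread_scale`` broadens the membership-weighted standard deviations;
    the default of 2 yields overlapping, smoothly interpolating rules (very
    narrow memberships degenerate into a nearest-centre lookup that
    generalises poorly).

    Guard: the consequent parameter count r·(d+1) must stay below the number
    of training rows, mirroring the exclusion of over-parameterised rule
    counts; violating it raises :class:`OverfittingGuardError`.
    """
    Xraw, y = _xy(train)
    n, d = Xraw.shape
    if r < 1:
        raise ValueError("r must be >= 1")
    n_params = r * (d + 1)
    if n_params >= n:
        raise OverfittingGuardError(
            f"{r} rules need {n_params} consequent parameters but only "
            f"{n} training rows are available"
        )
    x_scaler = Scaler.fit(Xraw)
    X = x_scaler.transform(Xraw)

    rng_range = X.max(axis=0) - X.min(axis=0)
    floor = np.maximum(spread_floor_frac * rng_range, 1e-12)
    if r == 1:
        centers = X.mean(axis=0, keepdims=True)
        spreads = np.maximum(X.std(axis=0, keepdims=True), floor)
    else:
        centers, U = fcm_cluster(X, r, fuzzifier=fuzzifier, seed=seed)
        Um = U ** fuzzifier
        spreads = np.empty_like(centers)
        for k in range(r):
            wk = Um[:, k]
            diff2 = (X - centers[k]) ** 2
            spreads[k] = np.sqrt((wk[:, None] * diff2).sum(axis=0) / wk.sum())
        spreads = np.maximum(spread_scale * spreads, floor)

    model = ANFISModel(r=r, centers=np.atleast_2d(centers), spreads=spreads,
                       consequents=np.zeros((r, d + 1)), x_scaler=x_scaler)
    _refit_consequents(model, X, y)
    return model


def _refit_consequents(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> None:
    wbar = _firing(model, X)
    Phi = _anfis_design(wbar, X)
    theta, *_ = np.linalg.lstsq(Phi, y, rcond=None)
    model.consequents = theta.reshape(model.r, -1)


def train_anfis_hybrid(
    model: ANFISModel,
    train: SupervisedSet | tuple,
    test: SupervisedSet | tuple,
    epochs: int = 100,
    learning_rate: float = 0.01,
    clip_norm: float = 3.0,
) -> tuple[ANFISModel, np.ndarray, np.ndarray]:
    """Hybrid learning: per epoch a least-squares forward pass refits the
    consequents, then a gradient backward pass updates centres and spreads
    (step ``learning_rate``, global gradient norm clipped at ``clip_norm``).

    RMSE on train and test is recorded after each forward pass; both curves
    (length ``epochs``) are returned along with the updated model.  On small
    noisy datasets the training curve typically keeps falling while the test
    curve rises — the overfitting signature of antecedent tuning.
    """
    Xtr_raw, ytr = _xy(train)
    Xte_raw, yte = _xy(test)
    model = ANFISModel(
        r=model.r, centers=model.centers.copy(), spreads=model.spreads.copy(),
        consequents=model.consequents.copy(), x_scaler=model.x_scaler,
        trained_epochs=model.trained_epochs,
    )
    Xtr = model.x_scaler.transform(Xtr_raw)
    Xte = model.x_scaler.transform(Xte_raw)
    floor = np.maximum(1e-3 * (Xtr.max(axis=0) - Xtr.min(axis=0)), 1e-12)
    train_curve = np.empty(epochs)
    test_curve = np.empty(epochs)
    for epoch in range(epochs):
        _refit_consequents(model, Xtr, ytr)
        rtr = _predict_std(model, Xtr) - ytr
        rte = _predict_std(model, Xte) - yte
        train_curve[epoch] = float(np.sqrt(np.mean(rtr ** 2)))
        test_curve[epoch] = float(np.sqrt(np.mean(rte ** 2)))
        if not (np.isfinite(train_curve[epoch]) and np.isfinite(test_curve[epoch])):
            raise NumericError(f"hybrid learning produced non-finite loss at epoch {epoch}")

        g_c, g_s = _antecedent_gradients(model, Xtr, ytr)
        norm = float(np.sqrt((g_c ** 2).sum() + (g_s ** 2).sum()))
        if norm > clip_norm:
            g_c *= clip_norm / norm
            g_s *= clip_norm / norm
        model.centers -= learning_rate * g_c
        model.spreads = np.maximum(model.spreads - learning_rate * g_s, floor)
        model.trained_epochs += 1
    # final forward pass so the returned model's consequents match its antecedents
    _refit_consequents(model, Xtr, ytr)
    return model, train_curve, test_curve


def _antecedent_gradients(
    model: ANFISModel, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of ½Σ(ŷ−y)² w.r.t. Gaussian centres and spreads."""
    n, d = X.shape
    wbar = _firing(model, X)                                   # N × r
    A1 = np.concatenate([np.ones((n, 1)), X], axis=1)
    rule_out = A1 @ model.consequents.T                        # N × r
    yhat = (wbar * rule_out).sum(axis=1)
    err = yhat - y                                             # N
    # d yhat / d wbar_k path: yhat = Σ wbar_k f_k, with wbar = w/Σw
    # ∂yhat/∂log w_k = wbar_k (f_k − yhat)
    g_logw = wbar * (rule_out - yhat[:, None])                 # N × r
    coef = err[:, None] * g_logw                               # N × r
    diff = X[:, None, :] - model.centers[None, :, :]           # N × r × d
    s2 = model.spreads ** 2
    g_c = (coef[:, :, None] * diff / s2[None, :, :]).sum(axis=0)
    g_s = (coef[:, :, None] * diff ** 2 / (s2 * model.spreads)[None, :, :]).sum(axis=0)
    return g_c, g_s


# -------------------------------------------------------------- predict -----

def predict_baseline(model, X: np.ndarray) -> np.ndarray:
    """Predict with any baseline model (dispatch on type)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(model, LinearModel):
        if X.shape[1] != model.coefficients.shape[0]:
            raise ValueError("feature dimension mismatch")
        return X @ model.coefficients + model.intercept
    if isinstance(model, NNModel):
        if X.shape[1] != model.W1.shape[1]:
            raise ValueError("feature dimension mismatch")
        A = _sigmoid(model.x_scaler.transform(X) @ model.W1.T + model.b1)
        return (A @ model.w2 + model.b2) * model.y_scale + model.y_mean
    if isinstance(model, ANFISModel):
        if X.shape[1] != model.centers.shape[1]:
            raise ValueError("feature dimension mismatch")
        return _predict_std(model, model.x_scaler.transform(X))
    raise ConfigurationError(f"unknown model type {type(model).__name__}")


def _predict_std(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """ANFIS prediction on already-standardised inputs."""
    wbar = _firing(model, X)
    A1 = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    return (wbar * (A1 @ model.consequents.T)).sum(axis=1)


# ---------------------------------------------------------------- helpers ---

def _xy(train) -> tuple[np.ndarray, np.ndarray]:
    """Accept a SupervisedSet or a plain (X, y) pair."""
    if isinstance(train, SupervisedSet):
        return train.X, train.T
    X, y = train
    return np.atleast_2d(np.asarray(X, dtype=float)), np.asarray(y, dtype=float).ravel()
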