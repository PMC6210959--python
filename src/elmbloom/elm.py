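"""Extreme learning machine regression.

An ELM is a single-hidden-layer feedforward network whose hidden-layer
weights ``W`` and biases ``b`` are drawn randomly once and never updated;
only the output weights ``beta`` are fitted, by a minimum-norm least-squares
solve against the hidden-layer output matrix ``H``:

    f_L(x) = sum_i beta_i * G(w_i, b_i, x),      beta = H⁺ T

where ``H⁺`` is the Moore–Penrose pseudoinverse.  Training is therefore a
single linear solve — three steps: draw the hidden layer, build H, solve for
beta.  Supported hidden-node types: ``sigmoid`` (1/(1+exp(−(w·x+b)))),
``rbf`` (exp(−(b·‖x−w‖)²), b > 0) and ``sine`` (sin(w·x+b)).

Hidden nodes are seeded per-node, so the layer for ``L+1`` nodes extends the
layer for ``L`` nodes under the same seed.  This makes training error
monotone non-increasing in L for a fixed seed and dataset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data import SupervisedSet
from .exceptions import ConfigurationError, FormatError, NumericError

ACTIVATIONS = ("sigmoid", "rbf", "sine")


@dataclasses.dataclass(frozen=True)
class HiddenLayer:
    """Frozen random hidden layer: W (L×d), b (length L), activation kind."""

    W: np.ndarray
    b: np.ndarray
    activation: str
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "W", np.atleast_2d(np.asarray(self.W, dtype=float)))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).ravel())
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.W.shape[0] != self.b.shape[0]:
            raise ValueError("rows(W) must equal len(b)")
        if self.L < 1:
            raise ValueError("hidden layer needs at least one node")
        if self.activation == "rbf" and not (self.b > 0).all():
            raise ValueError("rbf biases (kernel widths) must be strictly positive")

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]


@dataclasses.dataclass(frozen=True)
class Scaler:
    """Per-feature affine standardisation learned on training data."""

    mean: np.ndarray
    scale: np.ndarray  # std with zero-variance features mapped to scale 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    @classmethod
    def identity(cls, d: int) -> "Scaler":
        return cls(mean=np.zeros(d), scale=np.ones(d))


@dataclasses.dataclass(frozen=True)
class ELMModel:
    """A trained ELM: frozen hidden layer, fitted output weights, input scaler."""

    hidden: HiddenLayer
    beta: np.ndarray
    scaler: Scaler
    d: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float).ravel())
        if self.beta.shape[0] != self.hidden.L:
            raise ValueError("len(beta) must equal the hidden-node count")
        if self.scaler.mean.shape[0] != self.d:
            raise ValueError("scaler dimension must match input dimension")


def activation(kind: str, w: np.ndarray, b: float, x: np.ndarray) -> float:
    """Evaluate one hidden node G(w, b, x) at a single input vector."""
    w = np.asarray(w, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if kind == "sigmoid":
        return float(1.0 / (1.0 + np.exp(-(w @ x + b))))
    if kind == "rbf":
        return float(np.exp(-((b * np.linalg.norm(x - w)) ** 2)))
    if kind == "sine":
        return float(np.sin(w @ x + b))
    raise ConfigurationError(f"unknown activation {kind!r}")


def init_hidden(
    L: int, d: int, activation: str = "sigmoid", seed: int = 0,
    weight_scale: float | str = "auto",
) -> HiddenLayer:
    """Draw a random hidden layer: W, b i.i.d. uniform, W on [−s, s].

    ``weight_scale="auto"`` sets s = 1/√d, which keeps the pre-activation
    variance — and hence the effective bandwidth of the random feature map —
    invariant to the input dimension.  This matters when models with
    different feature-set sizes are compared on the same data: with a fixed
    s the larger feature set would get systematically steeper hidden units.
    Pass ``weight_scale=1.0`` for plain uniform [−1, 1] weights.  Biases are
    uniform on [−1, 1]; RBF kernel widths are uniform on (0, 1].

    Each node has its own seeded stream derived from ``(seed, node_index)``,
    so layers are nested across L for the same seed and fully reproducible.
    """
    if L < 1 or d < 1:
        raise ValueError(f"L and d must be >= 1, got L={L}, d={d}")
    scale = 1.0 / np.sqrt(d) if weight_scale == "auto" else float(weight_scale)
    W = np.empty((L, d))
    b = np.empty(L)
    for i in range(L):
        rng = np.random.default_rng([seed, i])
        W[i] = scale * rng.uniform(-1.0, 1.0, size=d)
        if activation == "rbf":
            b[i] = 1.0 - rng.uniform(0.0, 1.0)  # uniform on (0, 1]
        else:
            b[i] = rng.uniform(-1.0, 1.0)
    return HiddenLayer(W=W, b=b, activation=activation, seed=seed)


def hidden_matrix(hidden: HiddenLayer, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix H with H[i, j] = G(w_j, b_j, x_i)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != hidden.d:
        raise ValueError(f"X has {X.shape[1]} columns, hidden layer expects {hidden.d}")
    if hidden.activation == "sigmoid":
        Z = X @ hidden.W.T + hidden.b
        H = 1.0 / (1.0 + np.exp(-Z))
    elif hidden.activation == "sine":
        H = np.sin(X @ hidden.W.T + hidden.b)
    else:  # rbf
        # ‖x_i − w_j‖² expanded to avoid an N×L×d intermediate
        sq = (
            (X ** 2).sum(axis=1)[:, None]
            - 2.0 * X @ hidden.W.T
            + (hidden.W ** 2).sum(axis=1)[None, :]
        )
        np.maximum(sq, 0.0, out=sq)
        H = np.exp(-(hidden.b ** 2) * sq)
    if not np.isfinite(H).all():
        raise NumericError("non-finite entries in hidden output matrix")
    return H


def fit_output_weights(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = H⁺ T.

    Solved by SVD; singular values below ``max(N, L)·eps·σ_max`` are treated
    as zero, so rank-deficient H is handled without forming (HᵀH)⁻¹.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    T = np.asarray(T, dtype=float).ravel()
    if not (np.isfinite(H).all() and np.isfinite(T).all()):
        raise NumericError("non-finite entries passed to the least-squares solve")
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T row counts disagree")
    rcond = max(H.shape) * np.finfo(float).eps
    beta, *_ = np.linalg.lstsq(H, T, rcond=rcond)
    return beta


def train_elm(
    train: SupervisedSet,
    L: int,
    activation: str = "sigmoid",
    seed: int = 0,
    standardize: bool = True,
    weight_scale: float | str = "auto",
) -> ELMModel:
    """Train an ELM: learn the input scaler on the training rows, draw the
    hidden layer, and fit beta in one least-squares solve.  No iterative
    updates occur; the hidden layer is never touched after the draw."""
    scaler = Scaler.fit(train.X) if standardize else Scaler.identity(train.d)
    hidden = init_hidden(L, train.d, activation=activation, seed=seed,
                         weight_scale=weight_scale)
    H = hidden_matrix(hidden, scaler.transform(train.X))
    beta = fit_output_weights(H, train.T)
    return ELMModel(hidden=hidden, beta=beta, scaler=scaler, d=train.d)


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Evaluate f_L(x) = Σ beta_j G(w_j, b_j, x) on scaled inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {model.d}")
    H = hidden_matrix(model.hidden, model.scaler.transform(X))
    return H @ model.beta


def save_model(model: ELMModel, path: str | Path) -> None:
    """Serialise to JSON; round-trips exactly (hex floats)."""
    def enc(a: np.ndarray) -> list:
        return [[v.hex() for v in row] for row in np.atleast_2d(np.asarray(a, dtype=float))]

    payload = {
        "kind": "elm",
        "activation": model.hidden.activation,
        "seed": model.hidden.seed,
        "d": model.d,
        "W": enc(model.hidden.W),
        "b": enc(model.hidden.b)[0],
        "beta": enc(model.beta)[0],
        "scaler_mean": enc(model.scaler.mean)[0],
        "scaler_scale": enc(model.scaler.scale)[0],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ELMModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "elm":
        raise FormatError(f"not an ELM model file (kind={payload.get('kind')!r})")
    dec1 = lambda row: np.array([float.fromhex(v) for v in row])
    dec2 = lambda rows: np.array([[float.fromhex(v) for v in row] for row in rows])
    hidden = HiddenLayer(
        W=dec2(payload["W"]), b=dec1(payload["b"]),
        activation=payload["activation"], seed=payload["seed"],
    )
    scaler = Scaler(mean=dec1(payload["scaler_mean"]), scale=dec1(payload["scaler_scale"]))
    return ELMModel(hidden=hidden, beta=dec1(payload["beta"]), scaler=scaler, d=payload["d"])
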