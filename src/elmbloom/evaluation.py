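"""Model evaluation: error metrics, hidden-node selection, descriptive
statistics, model comparison grids and improvement percentages.

The headline skill score is the Nash–Sutcliffe form of R²,

    R² = 1 − Σ(Y − Ŷ)² / Σ(Y − Ȳ)²,

which equals 1 for a perfect prediction, 0 for the climatological mean and
can be negative.  RMSE is reported in μg/L.  AIC uses the Gaussian
log-likelihood form n·ln(SSE/n) + 2k with k the number of fitted
parameters (ELM: L output weights; linear regression: d+1; ANFIS: r·(d+1)
consequents; NN: all weights and biases).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines as bl
from . import elm as elm_mod
from .data import SiteSeries, SupervisedSet, TrainTestSplit
from .exceptions import ConfigurationError

__all__ = [
    "FitReport", "NodeSweep", "ComparisonReport",
    "rmse", "r_squared", "aic", "pearson_corr", "descriptive_stats",
    "evaluate_model", "improvement_percent", "select_hidden_nodes",
    "compare_models",
]


@dataclasses.dataclass
class FitReport:
    """Train/test R², RMSE and AIC for one fitted model."""

    model_label: str
    r2_train: float
    r2_test: float
    rmse_train: float   # μg/L
    rmse_test: float    # μg/L
    aic_train: float
    aic_test: float
    L_or_r: int | None = None
    seeds_used: int = 1

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class NodeSweep:
    """Hidden-node sweep result: per-L mean train/test RMSE and the argmin."""

    L_values: list[int]
    train_rmse: list[float]
    test_rmse: list[float]
    selected_L: int
    flagged: list[int] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"L": self.L_values, "train_rmse": self.train_rmse, "test_rmse": self.test_rmse}
        )


@dataclasses.dataclass
class ComparisonReport:
    """Model label → FitReport, all computed on one shared split."""

    reports: dict[str, FitReport]
    failures: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports.values()])


# ---------------------------------------------------------------- metrics ---

def rmse(Y: Sequence[float], Yhat: Sequence[float]) -> float:
    """Root-mean-square error, sqrt(mean((Ŷ − Y)²))."""
    Y = np.asarray(Y, dtype=float).ravel()
    Yhat = np.asarray(Yhat, dtype=float).ravel()
    if Y.shape != Yhat.shape or Y.size == 0:
        raise ValueError("rmse needs two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((Yhat - Y) ** 2)))


def r_squared(Y: Sequence[float], Yhat: Sequence[float], squared_pearson: bool = False) -> float:
    """Skill score 1 − Σ(Y−Ŷ)²/Σ(Y−Ȳ)² (Nash–Sutcliffe form; may be < 0).

    With ``squared_pearson=True`` returns the squared Pearson correlation of
    Y and Ŷ instead.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    Yhat = np.asarray(Yhat, dtype=float).ravel()
    if Y.shape != Yhat.shape or Y.size < 2:
        raise ValueError("r_squared needs two equal-length vectors with n >= 2")
    sstot = float(((Y - Y.mean()) ** 2).sum())
    if sstot == 0.0:
        raise ValueError("r_squared undefined for a constant observation vector")
    if squared_pearson:
        return float(pearson_corr(Y, Yhat) ** 2)
    return 1.0 - float(((Y - Yhat) ** 2).sum()) / sstot


def aic(n: int, sse: float, k: int) -> float:
    """Akaike information criterion, Gaussian form n·ln(SSE/n) + 2k."""
    if n <= 0:
        raise ValueError("n must be positive")
    if sse <= 0:
        raise ValueError("AIC undefined for SSE <= 0 (perfect fit)")
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(n * math.log(sse / n) + 2 * k)


def pearson_corr(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("pearson_corr needs equal-length vectors with n >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("pearson_corr undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def descriptive_stats(series: SiteSeries) -> pd.DataFrame:
    """Mean, min and max per variable (the descriptive-table layout)."""
    frame = series.frame.drop(columns=["week_start"])
    if frame.dropna(how="all").empty:
        raise ValueError("empty series")
    return pd.DataFrame(
        {"mean": frame.mean(), "min": frame.min(), "max": frame.max()}
    )


# --------------------------------------------------------------- reports ----

def _predict_any(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, elm_mod.ELMModel):
        return elm_mod.predict(model, X)
    return bl.predict_baseline(model, X)


def _param_count(model, d: int) -> int:
    if isinstance(model, elm_mod.ELMModel):
        return model.hidden.L
    if isinstance(model, bl.LinearModel):
        return d + 1
    if isinstance(model, bl.ANFISModel):
        return model.r * (d + 1)
    if isinstance(model, bl.NNModel):
        h = model.hidden_nodes
        return h * d + h + h + 1
    raise ConfigurationError(f"unknown model type {type(model).__name__}")


def evaluate_model(
    model, split: TrainTestSplit, label: str = "", k: int | None = None,
    L_or_r: int | None = None, seeds_used: int = 1,
) -> FitReport:
    """Compute the six-metric report (R², RMSE, AIC on train and test)."""
    if k is None:
        k = _param_count(model, split.train.d)
    rows = {}
    for part, sset in [("train", split.train), ("test", split.test)]:
        yhat = _predict_any(model, sset.X)
        sse = float(((sset.T - yhat) ** 2).sum())
        rows[f"r2_{part}"] = r_squared(sset.T, yhat)
        rows[f"rmse_{part}"] = rmse(sset.T, yhat)
        rows[f"aic_{part}"] = aic(sset.n, sse, k) if sse > 0 else float("-inf")
    return FitReport(model_label=label or type(model).__name__,
                     L_or_r=L_or_r, seeds_used=seeds_used, **rows)


def improvement_percent(before: FitReport, after: FitReport) -> dict[str, float]:
    """Percentage change from ``before`` to ``after``, positive = improvement.

    R² improves upward: (after − before)/before × 100.  RMSE improves
    downward: (before − after)/before × 100.  Values are full precision;
    round to 1 decimal for display.  Zero denominators yield NaN.
    """
    out: dict[str, float] = {}
    for metric in ("r2_train", "r2_test"):
        b, a = getattr(before, metric), getattr(after, metric)
        out[metric] = (a - b) / b * 100.0 if b != 0 else float("nan")
    for metric in ("rmse_train", "rmse_test"):
        b, a = getattr(before, metric), getattr(after, metric)
        out[metric] = (b - a) / b * 100.0 if b != 0 else float("nan")
    return out


# ----------------------------------------------------------------- sweep ----

def select_hidden_nodes(
    train: SupervisedSet,
    test: SupervisedSet,
    L_range: Sequence[int] = range(2, 31),
    activation: str = "sigmoid",
    seeds: Sequence[int] = (0,),
    standardize: bool = True,
) -> NodeSweep:
    """Sweep the hidden-node count and select the test-RMSE minimiser.

    For each candidate L the ELM is trained over each seed in ``seeds`` and
    the mean train/test RMSE recorded; ``selected_L`` is the argmin of mean
    test RMSE with ties broken toward smaller L.  Candidates whose training
    goes numerically unstable are flagged (RMSE recorded as inf), not fatal.
    """
    L_values = sorted(set(int(L) for L in L_range))
    if not L_values:
        raise ValueError("empty candidate range")
    tr_means, te_means, flagged = [], [], []
    for L in L_values:
        tr, te = [], []
        for seed in seeds:
            try:
                model = elm_mod.train_elm(train, L, activation=activation,
                                          seed=int(seed), standardize=standardize)
                tr.append(rmse(train.T, elm_mod.predict(model, train.X)))
                te.append(rmse(test.T, elm_mod.predict(model, test.X)))
            except Exception:
                tr.append(float("inf"))
                te.append(float("inf"))
        m_tr, m_te = float(np.mean(tr)), float(np.mean(te))
        if not (np.isfinite(m_tr) and np.isfinite(m_te)):
            flagged.append(L)
        tr_means.append(m_tr)
        te_means.append(m_te)
    selected = L_values[int(np.argmin(te_means))]  # argmin takes first (smallest L) on ties
    return NodeSweep(L_values=L_values, train_rmse=tr_means, test_rmse=te_means,
                     selected_L=selected, flagged=flagged)


# ------------------------------------------------------------- comparison ---

DEFAULT_COMPARISON = {
    "ELM2": {"kind": "elm", "L": 10, "activation": "sigmoid", "seeds": (0,)},
    "Multiple LR": {"kind": "linear"},
    "NN with BP": {"kind": "nn", "hidden_nodes": 10, "learning_rate": 0.001,
                   "epochs": 1000, "seed": 0},
    "ANFIS-FCM (r=2)": {"kind": "anfis", "r": 2},
    "ANFIS-FCM (r=3)": {"kind": "anfis", "r": 3},
}


def compare_models(split: TrainTestSplit, config: Mapping[str, Mapping] | None = None) -> ComparisonReport:
    """Train and evaluate a set of models on one shared split.

    ``config`` maps a display label to a model description
    (``kind`` ∈ {elm, linear, nn, anfis} plus per-kind options).  ELM rows
    may average metrics over several hidden-layer seeds.  A model that
    fails is recorded in ``failures``; the run continues.
    """
    config = dict(config) if config is not None else dict(DEFAULT_COMPARISON)
    reports: dict[str, FitReport] = {}
    failures: dict[str, str] = {}
    for label, desc in config.items():
        try:
            reports[label] = _run_one(label, dict(desc), split)
        except Exception as exc:  # per-cell failure tolerance
            failures[label] = f"{type(exc).__name__}: {exc}"
    return ComparisonReport(reports=reports, failures=failures)


def _run_one(label: str, desc: dict, split: TrainTestSplit) -> FitReport:
    kind = desc.pop("kind")
    if kind == "elm":
        seeds = [int(s) for s in desc.pop("seeds", (0,))]
        L = int(desc.pop("L"))
        parts = [
            evaluate_model(
                elm_mod.train_elm(split.train, L, seed=s, **desc), split,
                label=label, L_or_r=L,
            )
            for s in seeds
        ]
        mean = lambda attr: float(np.mean([getattr(p, attr) for p in parts]))
        return FitReport(
            model_label=label,
            r2_train=mean("r2_train"), r2_test=mean("r2_test"),
            rmse_train=mean("rmse_train"), rmse_test=mean("rmse_test"),
            aic_train=mean("aic_train"), aic_test=mean("aic_test"),
            L_or_r=L, seeds_used=len(seeds),
        )
    if kind == "linear":
        return evaluate_model(bl.fit_linear_regression(split.train), split, label=label)
    if kind == "nn":
        model = bl.train_nn_bp(split.train, **desc)
        return evaluate_model(model, split, label=label, L_or_r=model.hidden_nodes)
    if kind == "anfis":
        r = int(desc.pop("r"))
        return evaluate_model(bl.build_anfis_fcm(split.train, r, **desc), split,
                              label=label, L_or_r=r)
    raise ConfigurationError(f"unknown model kind {kind!r}")
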