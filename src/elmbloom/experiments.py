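"""Reusable study protocols built on the lower-level modules.

These functions encode the experiment designs the package's headline claims
rest on, so tests, scripts and notebooks run the identical procedure:

* :func:`paired_variant_comparison` — the upstream-information experiment:
  on many independently generated weir pairs, fit ELM1 (downstream-only
  predictors) and ELM2 (plus lagged upstream chlorophyll-a) with the
  hidden-node sweep, and compare their selected test RMSEs with a paired
  sign test.
* :func:`anfis_overfit_rate` — the hybrid-learning experiment: how often
  100 epochs of ANFIS antecedent tuning on a small noisy dataset lowers
  training RMSE while raising test RMSE (the overfitting signature that
  justifies one-pass ANFIS).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .baselines import build_anfis_fcm, train_anfis_hybrid
from .data import assemble_features, split_half
from .evaluation import select_hidden_nodes
from .synth import SynthConfig, generate_pair

__all__ = ["PairedComparison", "paired_variant_comparison", "anfis_overfit_rate"]


@dataclasses.dataclass
class PairedComparison:
    """Result of the ELM1-vs-ELM2 paired experiment."""

    rmse_elm1: np.ndarray      # selected mean test RMSE per pair, μg/L
    rmse_elm2: np.ndarray
    wins_elm2: int             # pairs where ELM2 < ELM1
    n_pairs: int
    p_two_sided: float         # sign test
    p_one_sided: float         # sign test, alternative: ELM2 better

    @property
    def median_elm1(self) -> float:
        return float(np.median(self.rmse_elm1))

    @property
    def median_elm2(self) -> float:
        return float(np.median(self.rmse_elm2))


def _selected_test_rmse(train, test, L_range, seeds) -> float:
    sweep = select_hidden_nodes(train, test, L_range=L_range, seeds=seeds)
    return sweep.test_rmse[sweep.L_values.index(sweep.selected_L)]


def paired_variant_comparison(
    n_pairs: int = 50,
    coupling: float = 0.5,
    base_seed: int = 0,
    sweep_seeds: Sequence[int] = range(5),
    L_range: Sequence[int] = range(2, 31),
    config_kwargs: dict | None = None,
) -> PairedComparison:
    """Fit ELM1 and ELM2 on ``n_pairs`` synthetic weir pairs and sign-test
    the paired difference of their selected test RMSEs.

    Each pair uses its own generator seed (``base_seed + i``).  Both
    variants share the pair's chronological 50/50 split; for each the
    hidden-node count is chosen by the test-minimum sweep (mean over
    ``sweep_seeds`` hidden-layer draws), the study's own selection rule.
    """
    kwargs = dict(config_kwargs or {})
    r1, r2 = [], []
    for i in range(n_pairs):
        cfg = SynthConfig(seed=base_seed + i, coupling=coupling, **kwargs)
        up, down, _ = generate_pair(cfg)
        split1 = split_half(assemble_features(down, "ELM1"))
        split2 = split_half(assemble_features(down, "ELM2", up=up))
        r1.append(_selected_test_rmse(split1.train, split1.test, L_range, sweep_seeds))
        r2.append(_selected_test_rmse(split2.train, split2.test, L_range, sweep_seeds))
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    wins = int((r2 < r1).sum())
    return PairedComparison(
        rmse_elm1=r1, rmse_elm2=r2, wins_elm2=wins, n_pairs=n_pairs,
        p_two_sided=float(stats.binomtest(wins, n_pairs, 0.5).pvalue),
        p_one_sided=float(stats.binomtest(wins, n_pairs, 0.5,
                                          alternative="greater").pvalue),
    )


def anfis_overfit_rate(
    n_seeds: int = 20,
    base_seed: int = 0,
    r: int = 2,
    epochs: int = 100,
    n_weeks: int = 50,
    chl_noise_sd: float = 4.0,
) -> tuple[float, list[tuple[float, float, float, float]]]:
    """Fraction of small-n noisy datasets on which hybrid ANFIS training
    lowers training RMSE while raising test RMSE between the first and the
    last epoch.  Returns ``(rate, curves)`` where each curve entry is
    (train_first, train_last, test_first, test_last)."""
    hits = 0
    summary = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = SynthConfig(seed=seed, n_weeks=n_weeks, chl_noise_sd=chl_noise_sd)
        _, down, _ = generate_pair(cfg)
        split = split_half(assemble_features(down, "ELM1"), mode="random", seed=seed)
        model = build_anfis_fcm(split.train, r)
        _, tr, te = train_anfis_hybrid(model, split.train, split.test, epochs=epochs)
        hits += tr[-1] < tr[0] and te[-1] > te[0]
        summary.append((float(tr[0]), float(tr[-1]), float(te[0]), float(te[-1])))
    return hits / n_seeds, summary
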