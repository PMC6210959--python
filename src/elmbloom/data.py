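"""Weekly water-quality series: domain types, CSV I/O, feature assembly, splitting.

A monitoring site contributes one weekly record per calendar week with air
temperature (AT, °C, weekly mean), rainfall (RF, mm, weekly accumulation),
solar radiation (SR, MJ/m², weekly mean of daily totals), total nitrogen
(TN, mg/L), total phosphorus (TP, mg/L), the N/P ratio (NP = TN/TP) and
chlorophyll-a (Chla, μg/L).  Supervised sets for the two model variants are
assembled from these series:

* ``ELM1`` — downstream drivers at week *t* plus downstream Chla at *t−1*
  (the "7 days prior" autoregressive term); 7 predictors.
* ``ELM2`` — ELM1 plus upstream chlorophyll-a at *t−1*; 8 predictors.

Exogenous drivers enter contemporaneously at the target week; only the
chlorophyll terms are lagged.  Both lags are configurable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FormatError,
    InsufficientDataError,
)

#: Canonical weekly CSV column order; NP is optional on input (recomputed).
WEEKLY_COLUMNS = ["week_start", "AT", "RF", "SR", "TN", "TP", "NP", "Chla"]
MANDATORY_COLUMNS = ["week_start", "AT", "RF", "SR", "TN", "TP", "Chla"]
DAILY_COLUMNS = ["date", "air_temp", "rainfall", "solar"]

#: Canonical predictor names for the ELM1 variant, in assembly order.
ELM1_FEATURES = ["AT", "RF", "SR", "TN", "TP", "NP", "Chla_lag1"]
ELM2_FEATURES = ELM1_FEATURES + ["Chla_u_lag1"]

_NP_RTOL = 1e-6

_WEEKDAYS = {
    "monday": 0, "tuesday": 1, "wednesday": 2, "thursday": 3,
    "friday": 4, "saturday": 5, "sunday": 6,
}


@dataclasses.dataclass(frozen=True)
class DailyWeather:
    """One day of weather observations."""

    date: dt.date
    air_temp: float  # °C
    rainfall: float  # mm/day, >= 0
    solar: float     # MJ/m²/day, >= 0

    def __post_init__(self) -> None:
        if self.rainfall < 0:
            raise ValueError(f"rainfall must be >= 0, got {self.rainfall}")
        if self.solar < 0:
            raise ValueError(f"solar must be >= 0, got {self.solar}")


class SiteSeries:
    """Ordered weekly records for one monitoring site.

    Backed by a :class:`pandas.DataFrame` with the canonical columns.
    Validates on construction: strictly increasing ``week_start``,
    non-negative RF and Chla, and NP consistent with TN/TP to a relative
    tolerance of 1e-6 wherever all three are present.  Gaps (consecutive
    weeks more than 7 days apart) are allowed but recorded in ``gaps``.
    """

    def __init__(self, site_id: str, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        frame["week_start"] = pd.to_datetime(frame["week_start"])
        frame = frame.sort_values("week_start").reset_index(drop=True)
        if "NP" not in frame.columns:
            frame["NP"] = frame["TN"] / frame["TP"]
        frame = frame[WEEKLY_COLUMNS]

        weeks = frame["week_start"]
        if weeks.duplicated().any():
            dup = weeks[weeks.duplicated()].iloc[0]
            raise FormatError(f"duplicate week_start {dup.date()}")
        deltas = weeks.diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            raise FormatError("week_start must be strictly increasing")

        for col, lo in [("RF", 0.0), ("Chla", 0.0)]:
            vals = frame[col].dropna()
            if (vals < lo).any():
                raise FormatError(f"{col} must be >= {lo}")
        mask = frame[["TN", "TP", "NP"]].notna().all(axis=1)
        if mask.any():
            sub = frame.loc[mask]
            if (sub["TP"] <= 0).any():
                raise FormatError("TP must be > 0 wherever NP is present")
            expected = sub["TN"] / sub["TP"]
            bad = ~np.isclose(sub["NP"], expected, rtol=_NP_RTOL, atol=0.0)
            if bad.any():
                row = sub.index[bad][0]
                raise FormatError(
                    f"NP inconsistent with TN/TP at week {sub.loc[row, 'week_start'].date()}"
                )

        self.site_id = site_id
        self.frame = frame
        #: week_start values followed by a gap longer than 7 days
        self.gaps = [
            weeks.iloc[i].date()
            for i in range(len(weeks) - 1)
            if (weeks.iloc[i + 1] - weeks.iloc[i]).days != 7
        ]

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"SiteSeries({self.site_id!r}, n={len(self)})"

    @property
    def week_anchor(self) -> int:
        """Weekday (0=Monday) that the weekly grid is anchored on."""
        days = pd.unique(self.frame["week_start"].dt.weekday)
        if len(days) != 1:
            raise FormatError("week_start values fall on inconsistent weekdays")
        return int(days[0])


@dataclasses.dataclass
class SupervisedSet:
    """Assembled predictor matrix and chlorophyll-a target for one variant."""

    X: np.ndarray                 # N × d, no missing entries
    T: np.ndarray                 # N targets, μg/L
    feature_names: list[str]
    week_index: pd.DatetimeIndex  # target weeks, length N
    variant: str                  # "ELM1" | "ELM2" | "custom"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        n, d = self.X.shape
        if len(self.T) != n or len(self.week_index) != n:
            raise ValueError("X, T and week_index lengths disagree")
        if len(self.feature_names) != d:
            raise ValueError("feature_names does not match X columns")
        if not (np.isfinite(self.X).all() and np.isfinite(self.T).all()):
            raise ValueError("SupervisedSet must have no missing entries")
        if self.variant == "ELM1" and d != 7:
            raise ValueError(f"ELM1 requires d=7, got {d}")
        if self.variant == "ELM2" and d != 8:
            raise ValueError(f"ELM2 requires d=8, got {d}")

    @property
    def n(self) -> int:
        return len(self.T)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: Sequence[int]) -> "SupervisedSet":
        idx = np.asarray(idx, dtype=int)
        return SupervisedSet(
            X=self.X[idx], T=self.T[idx],
            feature_names=list(self.feature_names),
            week_index=self.week_index[idx], variant=self.variant,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.X, columns=self.feature_names)
        out.insert(0, "week_start", self.week_index)
        out["target"] = self.T
        return out


@dataclasses.dataclass
class TrainTestSplit:
    """A 50/50 train/test partition of a :class:`SupervisedSet`."""

    train: SupervisedSet
    test: SupervisedSet
    mode: str            # "chronological" | "random"
    seed: int | None


def read_weekly_csv(path: str | Path, site_id: str | None = None) -> SiteSeries:
    """Read a weekly site CSV (``week_start,AT,RF,SR,TN,TP,NP,Chla``).

    NP is recomputed from TN/TP when absent; rows are sorted by week_start.
    A ``site`` column, if present, supplies the site id.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")

    if site_id is None:
        if "site" in raw.columns and raw["site"].notna().any():
            site_id = str(raw["site"].dropna().iloc[0])
        else:
            site_id = path.stem

    frame = pd.DataFrame()
    try:
        frame["week_start"] = pd.to_datetime(raw["week_start"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: unparsable week_start: {exc}") from None
    numeric_cols = [c for c in WEEKLY_COLUMNS[1:] if c in raw.columns]
    for col in numeric_cols:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header occupies line 1
            raise FormatError(
                f"{path.name}: unparsable value {raw[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        frame[col] = parsed
    return SiteSeries(site_id, frame)


def write_weekly_csv(series: SiteSeries, path: str | Path) -> None:
    """Write the canonical weekly CSV; floats keep full round-trip precision."""
    out = series.frame.copy()
    out["week_start"] = out["week_start"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_daily_csv(path: str | Path) -> list[DailyWeather]:
    """Read a daily weather CSV (``date,air_temp,rainfall,solar``)."""
    path = Path(path)
    raw = pd.read_csv(path)
    missing = [c for c in DAILY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    dates = pd.to_datetime(raw["date"]).dt.date
    return [
        DailyWeather(d, float(a), float(r), float(s))
        for d, a, r, s in zip(dates, raw["air_temp"], raw["rainfall"], raw["solar"])
    ]


def aggregate_daily_to_weekly(
    daily: Sequence[DailyWeather], week_anchor: str | int = "monday"
) -> pd.DataFrame:
    """Aggregate daily weather to calendar weeks.

    AT and SR are weekly means of the available days; RF is the weekly
    accumulation.  Weeks with no daily record are omitted.  ``week_anchor``
    names the weekday each week starts on.

    Returns a DataFrame with columns ``week_start, AT, RF, SR``.
    """
    if len(daily) == 0:
        raise InsufficientDataError("no daily records to aggregate")
    anchor = _WEEKDAYS[week_anchor.lower()] if isinstance(week_anchor, str) else int(week_anchor)
    if not 0 <= anchor <= 6:
        raise ValueError(f"week_anchor must name a weekday, got {week_anchor!r}")

    rows = pd.DataFrame(
        {
            "date": [pd.Timestamp(d.date) for d in daily],
            "air_temp": [d.air_temp for d in daily],
            "rainfall": [d.rainfall for d in daily],
            "solar": [d.solar for d in daily],
        }
    )
    if not rows["date"].is_monotonic_increasing or rows["date"].duplicated().any():
        raise FormatError("daily dates must be strictly increasing")
    offset = (rows["date"].dt.weekday - anchor) % 7
    rows["week_start"] = rows["date"] - pd.to_timedelta(offset, unit="D")
    weekly = rows.groupby("week_start", sort=True).agg(
        AT=("air_temp", "mean"), RF=("rainfall", "sum"), SR=("solar", "mean")
    )
    return weekly.reset_index()


def _weekly_grid(frame: pd.DataFrame) -> pd.DataFrame:
    """Reindex a site frame onto a continuous 7-day grid (gaps become NaN)."""
    f = frame.set_index("week_start")
    grid = pd.date_range(f.index.min(), f.index.max(), freq="7D")
    return f.reindex(grid)


def assemble_features(
    down: SiteSeries,
    variant: str = "ELM1",
    up: SiteSeries | None = None,
    extra: Mapping[str, pd.Series] | None = None,
    chla_lag: int = 1,
    upstream_lag: int = 1,
    driver_lag: int = 0,
) -> SupervisedSet:
    """Assemble the supervised set for one model variant.

    For target week *t* the canonical predictors are AT, RF, SR, TN, TP and
    NP at week *t − driver_lag* (default 0, contemporaneous) and downstream
    Chla at *t − chla_lag* (default 1, the "7 days prior" term).  ``ELM2``
    appends upstream Chla at *t − upstream_lag*.  Extra named feature series
    (indexed by week_start) are appended after the canonical columns; rows
    with any missing predictor or target are dropped.
    """
    if variant not in ("ELM1", "ELM2", "custom"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    if variant == "ELM2" and up is None:
        raise ConfigurationError("variant ELM2 requires an upstream series")
    if chla_lag < 1:
        raise ConfigurationError("chla_lag must be >= 1 (the target may not predict itself)")

    grid = _weekly_grid(down.frame)
    cols = {}
    for name in ["AT", "RF", "SR", "TN", "TP", "NP"]:
        cols[name] = grid[name].shift(driver_lag)
    cols["Chla_lag1" if chla_lag == 1 else f"Chla_lag{chla_lag}"] = grid["Chla"].shift(chla_lag)

    if up is not None and variant in ("ELM2", "custom"):
        if up.week_anchor != down.week_anchor:
            raise ConfigurationError(
                "upstream and downstream series are anchored on different weekdays"
            )
        ugrid = _weekly_grid(up.frame).reindex(grid.index)
        name = "Chla_u_lag1" if upstream_lag == 1 else f"Chla_u_lag{upstream_lag}"
        cols[name] = ugrid["Chla"].shift(upstream_lag)

    if extra:
        for name, ser in extra.items():
            s = pd.Series(ser)
            s.index = pd.to_datetime(s.index)
            cols[str(name)] = s.reindex(grid.index)

    design = pd.DataFrame(cols, index=grid.index)
    design["__target__"] = grid["Chla"]
    design = design.dropna()
    if len(design) < 2:
        raise InsufficientDataError(
            f"only {len(design)} usable week(s) after lagging and dropping missing rows"
        )
    feature_names = [c for c in design.columns if c != "__target__"]
    # extra columns step outside the fixed-dimension ELM1/ELM2 contracts
    out_variant = "custom" if extra else variant
    return SupervisedSet(
        X=design[feature_names].to_numpy(dtype=float),
        T=design["__target__"].to_numpy(dtype=float),
        feature_names=feature_names,
        week_index=pd.DatetimeIndex(design.index),
        variant=out_variant,
    )


def split_half(
    sset: SupervisedSet, mode: str = "chronological", seed: int | None = None
) -> TrainTestSplit:
    """Split a supervised set 50/50 into train and test.

    Chronological mode puts the first ⌈N/2⌉ weeks in train; random mode
    permutes rows uniformly under ``seed`` first.  Week order is preserved
    within each part.
    """
    n = sset.n
    if n < 4:
        raise InsufficientDataError(f"need at least 4 rows to split, got {n}")
    if mode not in ("chronological", "random"):
        raise ConfigurationError(f"unknown split mode {mode!r}")
    n_train = math.ceil(n / 2)
    if mode == "chronological":
        train_idx = np.arange(n_train)
        test_idx = np.arange(n_train, n)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    return TrainTestSplit(
        train=sset.subset(train_idx), test=sset.subset(test_idx), mode=mode, seed=seed
    )


def write_supervised_csv(sset: SupervisedSet, path: str | Path) -> None:
    """Export as ``week_start,<feature_names...>,target``."""
    out = sset.to_frame()
    out["week_start"] = out["week_start"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
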