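"""Synthetic upstream/downstream weir-pair generator.

Emulates the statistical structure of weekly monitoring series at a pair of
river weirs in a temperate monsoon climate:

* air temperature and solar radiation follow annual sinusoids plus Gaussian
  noise (mean annual temperature ≈ 14 °C, mean daily solar ≈ 14.4 MJ/m²);
* weekly rainfall totals are right-skewed (gamma) with a summer-monsoon
  inflation of the scale, calibrated so annual totals fall around
  1000–1450 mm;
* total nitrogen and total phosphorus are positive mean-reverting AR(1)
  series with rainfall-driven runoff pulses (TN ≈ 2–4 mg/L,
  TP ≈ 0.03–0.09 mg/L); NP = TN/TP;
* chlorophyll-a follows a nonlinear driver response plus one-week
  autoregression: a temperature-gated logistic growth term scaled by
  phosphorus limitation and light, minus a rainfall flushing term.  The
  downstream site additionally receives ``coupling`` times the upstream
  chlorophyll-a lagged by ``coupling_lag`` weeks — the transfer an
  upstream-aware model can exploit.

All randomness flows from ``SynthConfig.seed`` through named substreams, so
changing one structural knob (e.g. ``coupling``) leaves every noise draw
unchanged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import DailyWeather, SiteSeries, WEEKLY_COLUMNS
from .elm import ELMModel, predict

__all__ = [
    "SynthConfig", "GroundTruth",
    "generate_weather", "generate_daily_weather", "generate_nutrients",
    "generate_pair", "sample_from_elm",
]


@dataclasses.dataclass
class SynthConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_weeks: int = 208                  # ≈ 4 years of weekly records
    start: str = "2013-01-07"           # a Monday; anchors the weekly grid
    seed: int = 0

    # weather
    temp_mean: float = 14.0             # °C, annual mean
    temp_amplitude: float = 11.0        # °C, annual half-range
    temp_noise_sd: float = 1.5
    solar_mean: float = 14.4            # MJ/m² per day, weekly mean
    solar_amplitude: float = 7.0
    solar_noise_sd: float = 2.0
    rain_shape: float = 0.7             # gamma shape of weekly totals
    rain_scale: float = 20.0            # mm, off-season gamma scale
    rain_season_peak_doy: int = 210     # late July monsoon peak
    rain_season_boost: float = 3.0      # scale multiplier amplitude at the peak
    rain_season_width: float = 28.0     # days, Gaussian width of the monsoon

    # nutrients
    TN_mean: float = 3.0                # mg/L
    TN_ar: float = 0.6
    TN_noise_sd: float = 0.25
    TN_rain_coef: float = 0.004         # mg/L per mm weekly rainfall anomaly
    TN_season_amplitude: float = 0.4    # winter-high seasonal swing, mg/L
    TP_mean: float = 0.055              # mg/L
    TP_ar: float = 0.6
    TP_noise_sd: float = 0.006
    TP_rain_coef: float = 0.00025
    TP_season_amplitude: float = 0.0

    # chlorophyll
    chl_base: float = 3.0               # μg/L baseline input per week
    growth_rate_max: float = 1.5        # /week, ceiling of the driver-dependent growth rate
    temp_thresh: float = 16.0           # °C, logistic gate midpoint
    temp_scale: float = 2.5             # °C, logistic gate width
    half_sat_TP: float = 0.03           # mg/L, phosphorus half-saturation
    flush_coef: float = 0.02            # per mm: washout exponent of weekly rainfall
    chl_K: float = 90.0                 # μg/L, self-limitation (carrying-capacity) scale
    chl_cap: float = 300.0              # μg/L hard ceiling of the recursion
    ar_coeff: float = 0.45              # 1-week chlorophyll autocorrelation
    coupling: float = 0.5               # upstream→downstream transfer weight
    coupling_lag: int = 1               # weeks
    chl_noise_sd: float = 3.0           # μg/L
    chl_floor: float = 0.1              # μg/L clamp
    shared_forcing_sd: float = 3.0      # μg/L, unmeasured forcing common to both sites
    shared_forcing_ar: float = 0.85     # persistence of the shared forcing

    def validate(self) -> None:
        bad = []
        if self.n_weeks < 8:
            bad.append("n_weeks must be >= 8")
        for f in ("temp_noise_sd", "solar_noise_sd", "TN_noise_sd",
                  "TP_noise_sd", "chl_noise_sd"):
            if getattr(self, f) < 0:
                bad.append(f"{f} must be >= 0")
        if not 0 <= self.ar_coeff < 1:
            bad.append("ar_coeff must be in [0, 1)")
        if not 0 <= self.coupling <= 1:
            bad.append("coupling must be in [0, 1]")
        if self.coupling_lag < 1:
            bad.append("coupling_lag must be >= 1")
        if self.rain_shape <= 0 or self.rain_scale <= 0:
            bad.append("rain_shape and rain_scale must be > 0")
        if self.TN_mean <= 0 or self.TP_mean <= 0:
            bad.append("nutrient means must be > 0")
        if self.shared_forcing_sd < 0:
            bad.append("shared_forcing_sd must be >= 0")
        if not 0 <= self.shared_forcing_ar < 1:
            bad.append("shared_forcing_ar must be in [0, 1)")
        if self.growth_rate_max < 0:
            bad.append("growth_rate_max must be >= 0")
        if self.chl_K <= 0:
            bad.append("chl_K must be > 0")
        if self.chl_cap <= self.chl_floor:
            bad.append("chl_cap must exceed chl_floor")
        if not 0 <= self.TN_ar < 1 or not 0 <= self.TP_ar < 1:
            bad.append("nutrient AR coefficients must be in [0, 1)")
        if bad:
            raise ValueError("invalid SynthConfig: " + "; ".join(bad))

    def _rng(self, stream: str) -> np.random.Generator:
        streams = ["weather", "nutrients_up", "nutrients_down", "chl_up",
                   "chl_down", "daily", "chl_shared"]
        key = streams.index(stream)
        return np.random.default_rng([int(self.seed), key])


@dataclasses.dataclass
class GroundTruth:
    """Noise-free latent chlorophyll series plus the coefficients used."""

    chl_up_latent: np.ndarray
    chl_down_latent: np.ndarray
    config: SynthConfig

    def to_frame(self, weeks: pd.DatetimeIndex) -> pd.DataFrame:
        return pd.DataFrame(
            {"week_start": weeks.strftime("%Y-%m-%d"),
             "chl_up_latent": self.chl_up_latent,
             "chl_down_latent": self.chl_down_latent}
        )


def _week_grid(config: SynthConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.start, periods=config.n_weeks, freq="7D")


def _seasonal(doy: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    # coldest/darkest around mid-January (day 15), warmest around mid-July
    return mean - amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)


def _monsoon_factor(doy: np.ndarray, config: SynthConfig) -> np.ndarray:
    delta = np.minimum(np.abs(doy - config.rain_season_peak_doy),
                       365.25 - np.abs(doy - config.rain_season_peak_doy))
    return 1.0 + config.rain_season_boost * np.exp(-0.5 * (delta / config.rain_season_width) ** 2)


def generate_weather(config: SynthConfig) -> pd.DataFrame:
    """Weekly AT (°C), RF (mm, accumulation) and SR (MJ/m²) series."""
    config.validate()
    weeks = _week_grid(config)
    doy = weeks.dayofyear.to_numpy(dtype=float) + 3.0  # mid-week day of year
    rng = config._rng("weather")
    at = _seasonal(doy, config.temp_mean, config.temp_amplitude) \
        + rng.normal(0.0, config.temp_noise_sd, config.n_weeks)
    sr = _seasonal(doy, config.solar_mean, config.solar_amplitude) \
        + rng.normal(0.0, config.solar_noise_sd, config.n_weeks)
    sr = np.maximum(sr, 0.5)
    scale = config.rain_scale * _monsoon_factor(doy, config)
    rf = rng.gamma(config.rain_shape, scale, size=config.n_weeks)
    return pd.DataFrame({"week_start": weeks, "AT": at, "RF": rf, "SR": sr})


def generate_daily_weather(config: SynthConfig) -> list[DailyWeather]:
    """Daily weather sampled from the same annual cycles (for exercising
    daily→weekly aggregation; weekly resolution is the primary product)."""
    config.validate()
    days = pd.date_range(config.start, periods=config.n_weeks * 7, freq="D")
    doy = days.dayofyear.to_numpy(dtype=float)
    rng = config._rng("daily")
    at = _seasonal(doy, config.temp_mean, config.temp_amplitude) \
        + rng.normal(0.0, config.temp_noise_sd, len(days))
    sr = np.maximum(
        _seasonal(doy, config.solar_mean, config.solar_amplitude)
        + rng.normal(0.0, config.solar_noise_sd, len(days)), 0.0)
    scale = config.rain_scale * _monsoon_factor(doy, config) / 7.0
    rf = rng.gamma(config.rain_shape, scale, size=len(days))
    return [
        DailyWeather(d.date(), float(a), float(r), float(s))
        for d, a, r, s in zip(days, at, rf, sr)
    ]


def generate_nutrients(
    config: SynthConfig, weather: pd.DataFrame, stream: str = "nutrients_down"
) -> pd.DataFrame:
    """Weekly TN, TP (mg/L, mean-reverting with rainfall pulses) and NP."""
    config.validate()
    rng = config._rng(stream)
    n = len(weather)
    doy = pd.DatetimeIndex(weather["week_start"]).dayofyear.to_numpy(dtype=float)
    rf_anom = weather["RF"].to_numpy() - config.rain_shape * config.rain_scale
    season_tn = config.TN_season_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    season_tp = config.TP_season_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)

    def ar1(mean, phi, sd, rain_coef, season):
        x = np.empty(n)
        eps = rng.normal(0.0, sd, n)
        x[0] = mean + season[0] + eps[0]
        for t in range(1, n):
            target = mean + season[t] + rain_coef * rf_anom[t]
            x[t] = target + phi * (x[t - 1] - (mean + season[t - 1])) + eps[t]
        return x

    tn = np.maximum(ar1(config.TN_mean, config.TN_ar, config.TN_noise_sd,
                        config.TN_rain_coef, season_tn), 0.3)
    tp = np.maximum(ar1(config.TP_mean, config.TP_ar, config.TP_noise_sd,
                        config.TP_rain_coef, season_tp), 0.005)
    return pd.DataFrame(
        {"week_start": weather["week_start"], "TN": tn, "TP": tp, "NP": tn / tp}
    )


def _growth_rate(config: SynthConfig, at, sr, tp) -> np.ndarray:
    """Driver-dependent weekly growth rate g(t) (dimensionless): a logistic
    temperature gate scaled by Monod phosphorus limitation and light."""
    gate = 1.0 / (1.0 + np.exp(-(at - config.temp_thresh) / config.temp_scale))
    p_lim = tp / (tp + config.half_sat_TP)
    light = sr / config.solar_mean
    return config.growth_rate_max * gate * p_lim * light


def _chl_series(config, rate, rf, inflow, noise) -> np.ndarray:
    """Multiplicative bloom recursion with rainfall washout.

        Chla(t) = base + inflow(t)
                  + (ar + g(t))·e^(−k·RF(t))·Chla(t−1) + ε(t)

    The standing biomass is carried over at a rate that rises with favourable
    temperature/nutrient/light conditions (transiently above 1: bloom
    growth), is knocked down multiplicatively by rainfall washout, and
    saturates through logistic self-limitation at scale ``chl_K``.  The
    rate × biomass and rain × biomass products are genuinely nonlinear in
    the assembled predictors.  Clamped to [chl_floor, chl_cap]."""
    n = len(rate)
    washed = (config.ar_coeff + rate) * np.exp(-config.flush_coef * rf)
    chl = np.empty(n)
    r0 = min(washed[0], 0.95)
    prev = float(np.clip((config.chl_base + inflow[0]) / (1.0 - r0),
                         config.chl_floor, config.chl_cap))
    for t in range(n):
        retention = washed[t] / (1.0 + prev / config.chl_K)
        chl[t] = config.chl_base + inflow[t] + retention * prev + noise[t]
        chl[t] = float(np.clip(chl[t], config.chl_floor, config.chl_cap))
        prev = chl[t]
    return chl


def generate_pair(config: SynthConfig) -> tuple[SiteSeries, SiteSeries, GroundTruth]:
    """Generate an (upstream, downstream) weir pair and the latent truth.

    Downstream chlorophyll receives ``coupling`` × upstream chlorophyll-a
    lagged ``coupling_lag`` weeks on top of its own driver response; the
    latent truth holds both chlorophyll recursions run without observation
    noise (drivers as realised).
    """
    config.validate()
    weather = generate_weather(config)
    nut_up = generate_nutrients(config, weather, "nutrients_up")
    nut_down = generate_nutrients(config, weather, "nutrients_down")
    at = weather["AT"].to_numpy()
    sr = weather["SR"].to_numpy()
    rf = weather["RF"].to_numpy()
    n = config.n_weeks

    g_up = _growth_rate(config, at, sr, nut_up["TP"].to_numpy())
    g_down = _growth_rate(config, at, sr, nut_down["TP"].to_numpy())

    # persistent forcing shared by both sites but absent from the emitted
    # predictors (unmeasured hydrology/cloudiness); part of the realised
    # environment, so it enters the latent truth as well
    phi = config.shared_forcing_ar
    innov = config._rng("chl_shared").normal(
        0.0, config.shared_forcing_sd * np.sqrt(1.0 - phi ** 2), n)
    shared = np.empty(n)
    shared[0] = innov[0] / np.sqrt(1.0 - phi ** 2) if phi > 0 else innov[0]
    for t in range(1, n):
        shared[t] = phi * shared[t - 1] + innov[t]
    noise_up = config._rng("chl_up").normal(0.0, config.chl_noise_sd, n) + shared
    noise_down = config._rng("chl_down").normal(0.0, config.chl_noise_sd, n) + shared

    zero = np.zeros(n)
    chl_up = _chl_series(config, g_up, rf, zero, noise_up)
    chl_up_latent = _chl_series(config, g_up, rf, zero, shared)

    lag = config.coupling_lag
    def _transfer(source: np.ndarray) -> np.ndarray:
        tr = np.empty(n)
        tr[lag:] = config.coupling * source[:-lag]
        tr[:lag] = config.coupling * source[0]
        return tr

    chl_down = _chl_series(config, g_down, rf, _transfer(chl_up), noise_down)
    chl_down_latent = _chl_series(config, g_down, rf, _transfer(chl_up_latent), shared)

    if max(chl_up_latent.max(), chl_down_latent.max()) >= config.chl_cap:
        raise ValueError(
            "divergent chlorophyll recursion: latent series hit chl_cap; "
            "reduce growth_rate_max/ar_coeff or increase flush_coef"
        )

    def site(site_id, nut, chl):
        frame = pd.DataFrame(
            {
                "week_start": weather["week_start"],
                "AT": at, "RF": rf, "SR": sr,
                "TN": nut["TN"], "TP": nut["TP"], "NP": nut["NP"],
                "Chla": chl,
            }
        )[WEEKLY_COLUMNS]
        return SiteSeries(site_id, frame)

    truth = GroundTruth(chl_up_latent=chl_up_latent,
                        chl_down_latent=chl_down_latent, config=config)
    return site("upstream", nut_up, chl_up), site("downstream", nut_down, chl_down), truth


def sample_from_elm(
    model: ELMModel, X: np.ndarray, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Targets drawn from a known ELM plus Gaussian noise (recovery oracle)."""
    yhat = predict(model, X)
    if noise_sd == 0.0:
        return yhat
    rng = np.random.default_rng(seed)
    return yhat + rng.normal(0.0, noise_sd, size=yhat.shape)
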