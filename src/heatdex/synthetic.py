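"""Synthetic indoor logger series with the structure the analysis assumes.

The generator emulates a multi-week, 15-minute indoor temperature/relative
humidity record from a hot semi-arid early-summer setting: a diurnal
temperature harmonic peaking in the late afternoon, persistent (AR(1))
sub-daily noise, day-to-day offsets, humidity anticorrelated with
temperature through the shared diurnal cycle (daytime heating lowers RH, so
RH peaks at night), and occasional evening convective-storm humidity spikes
with exponential decay.  Temperature and humidity are rescaled to exact
target sample marginals, so the configured means/SDs are reproduced by
construction while the temporal structure stays stochastic.

Defaults are calibrated to the published study setting: temperature
28.96 degC (SD 2.49), relative humidity 47.24 % (SD 7.63), peak near
17:30 local, readings every 15 minutes over a ~34-day window.

One root seed drives everything; it is split into three documented child
streams (temperature, humidity, storms) so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError, DomainError
from .indices import rh_to_dewpoint

__all__ = ["GeneratorConfig", "generate_series", "estimate_params", "FittedParams"]

_TZ_STUDY = timezone(timedelta(hours=2))

_RH_FLOOR = 0.1  # generated RH is clipped into (0, 100]


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic logger-series generator.

    Defaults reproduce the study conditions: a 15-minute series over
    2023-11-26 16:00 to 2023-12-30 08:45 (UTC+2) with the published
    temperature and humidity marginals.
    """

    model_config = {"frozen": True}

    start: datetime = datetime(2023, 11, 26, 16, 0, tzinfo=_TZ_STUDY)
    end: datetime = datetime(2023, 12, 30, 8, 45, tzinfo=_TZ_STUDY)
    interval_minutes: int = 15
    temp_mean: float = 28.96
    temp_sd: float = Field(default=2.49, ge=0.0)
    rh_mean: float = Field(default=47.24, gt=0.0, le=100.0)
    rh_sd: float = Field(default=7.63, ge=0.0)
    diurnal_amplitude: float = Field(default=3.0, ge=0.0)
    diurnal_peak_hour: float = Field(default=17.5, ge=0.0, lt=24.0)
    temp_rh_correlation: float = Field(default=-0.6, ge=-1.0, le=0.0)
    ar1_coefficient: float = Field(default=0.9, ge=0.0, lt=1.0)
    ar_noise_sd: float = Field(default=1.0, ge=0.0)
    day_offset_sd: float = Field(default=1.2, ge=0.0)
    storm_rate_per_day: float = Field(default=0.3, ge=0.0)
    storm_rh_boost: float = Field(default=15.0, ge=0.0)
    storm_decay_hours: float = Field(default=2.5, gt=0.0)
    seed: int = 0

    @field_validator("start", "end")
    @classmethod
    def _tz_aware(cls, v: datetime) -> datetime:
        if v.tzinfo is None or v.utcoffset() is None:
            raise ValueError("start/end must carry an explicit UTC offset")
        return v

    @field_validator("interval_minutes")
    @classmethod
    def _divides_hour(cls, v: int) -> int:
        if v <= 0 or 60 % v != 0:
            raise ValueError(f"interval_minutes={v} must divide 60")
        return v

    @model_validator(mode="after")
    def _ordered(self):
        if not self.end > self.start:
            raise ValueError("end must be after start")
        return self


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with unit marginal variance."""
    if phi == 0.0:
        return rng.normal(0.0, 1.0, n)
    eps = rng.normal(0.0, np.sqrt(1.0 - phi * phi), n)
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1) if x.size > 1 else 0.0
    if s == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def _rescale(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return mean + sd * _standardize(x)


def generate_series(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a reading series on the exact interval grid.

    Returns a DataFrame indexed by timezone-aware timestamps (inclusive of
    both endpoints when the end falls on the grid) with columns
    ``air_temp_c``, ``rel_humidity_pct`` and ``dew_point_c``.  Deterministic
    given ``config.seed``.
    """
    try:
        config = GeneratorConfig.model_validate(config)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(str(exc)) from exc

    idx = pd.date_range(config.start, config.end, freq=f"{config.interval_minutes}min")
    n = len(idx)
    if n < 2:
        raise ConfigurationError("configuration yields fewer than 2 readings")

    root = np.random.default_rng(config.seed)
    rng_t, rng_rh, rng_storm = root.spawn(3)

    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    omega = 2.0 * np.pi / 24.0
    diurnal = np.cos(omega * (hours - config.diurnal_peak_hour))

    day_idx = (idx.normalize() - idx[0].normalize()).days.to_numpy()
    day_offsets = rng_t.normal(0.0, config.day_offset_sd, int(day_idx.max()) + 1)
    t_raw = (
        config.diurnal_amplitude * diurnal
        + day_offsets[day_idx]
        + config.ar_noise_sd * _ar1(n, config.ar1_coefficient, rng_t)
    )
    air_temp = _rescale(t_raw, config.temp_mean, config.temp_sd)

    c = config.temp_rh_correlation
    eta = _ar1(n, config.ar1_coefficient, rng_rh)
    rh_shape = c * _standardize(t_raw) + np.sqrt(1.0 - c * c) * _standardize(eta)
    rh_raw = config.rh_sd * rh_shape + _storm_boost(idx, config, rng_storm)
    rel_humidity = np.clip(_rescale(rh_raw, config.rh_mean, config.rh_sd), _RH_FLOOR, 100.0)

    return pd.DataFrame(
        {
            "air_temp_c": air_temp,
            "rel_humidity_pct": rel_humidity,
            "dew_point_c": rh_to_dewpoint(air_temp, rel_humidity),
        },
        index=idx,
    ).rename_axis("timestamp")


def _storm_boost(
    idx: pd.DatetimeIndex, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-timed evening storm events, each an exponentially decaying
    RH boost (in % points) from its onset."""
    boost = np.zeros(len(idx))
    span_days = (idx[-1] - idx[0]) / pd.Timedelta(days=1)
    n_events = rng.poisson(config.storm_rate_per_day * span_days)
    if n_events == 0 or config.storm_rh_boost == 0.0:
        return boost
    n_days = int((idx.normalize()[-1] - idx.normalize()[0]).days) + 1
    hours_since_start = (idx - idx[0]) / pd.Timedelta(hours=1)
    for _ in range(n_events):
        day = int(rng.integers(0, n_days))
        onset_hour = float(rng.uniform(15.0, 22.0))  # convective storms: evening
        onset = idx.normalize()[0] + pd.Timedelta(days=day, hours=onset_hour)
        dt = hours_since_start - (onset - idx[0]) / pd.Timedelta(hours=1)
        active = dt >= 0.0
        boost[active] += config.storm_rh_boost * np.exp(
            -dt[active] / config.storm_decay_hours
        )
    return boost


@dataclass(frozen=True)
class FittedParams:
    """Generator parameters recovered from a reading series."""

    temp_mean: float
    temp_sd: float
    rh_mean: float
    rh_sd: float
    diurnal_amplitude: float
    diurnal_peak_hour: float
    ar1_coefficient: float
    temp_rh_correlation: float


def estimate_params(series: pd.DataFrame) -> FittedParams:
    """Recover marginal, diurnal and dependence parameters from a series.

    The diurnal cycle is estimated by a single-harmonic least-squares fit of
    temperature on cos/sin of local clock time; its amplitude and peak hour
    are the harmonic's amplitude and phase.  The AR(1) coefficient is the
    lag-1 autocorrelation of the harmonic residuals, and the temperature-
    humidity dependence is the plain Pearson correlation.

    Raises
    ------
    DomainError
        If the series spans fewer than 2 days (the harmonic and the
        day-to-day structure are not identifiable).
    """
    if len(series) < 3:
        raise DomainError("series too short to estimate parameters")
    idx = pd.DatetimeIndex(series.index)
    if (idx[-1] - idx[0]) < pd.Timedelta(days=2):
        raise DomainError("need at least 2 days of data to estimate parameters")

    t = series["air_temp_c"].to_numpy(dtype=float)
    rh = series["rel_humidity_pct"].to_numpy(dtype=float)
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0 + idx.second.to_numpy() / 3600.0
    omega = 2.0 * np.pi / 24.0
    design = np.column_stack([np.ones_like(hours), np.cos(omega * hours), np.sin(omega * hours)])
    coef, *_ = np.linalg.lstsq(design, t, rcond=None)
    _, a, b = coef
    amplitude = float(np.hypot(a, b))
    peak_hour = float((np.arctan2(b, a) / omega) % 24.0)

    resid = t - design @ coef
    r0 = resid.std()
    if r0 == 0.0:
        ar1 = 0.0
    else:
        ar1 = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])

    t_sd = t.std(ddof=1)
    rh_sd = rh.std(ddof=1)
    corr = 0.0 if t_sd == 0.0 or rh_sd == 0.0 else float(np.corrcoef(t, rh)[0, 1])
    return FittedParams(
        temp_mean=float(t.mean()),
        temp_sd=float(t_sd),
        rh_mean=float(rh.mean()),
        rh_sd=float(rh_sd),
        diurnal_amplitude=amplitude,
        diurnal_peak_hour=peak_hour,
        ar1_coefficient=ar1,
        temp_rh_correlation=corr,
    )
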