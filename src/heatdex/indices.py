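"""Thermal comfort indices from air temperature and relative humidity.

Two apparent-temperature indices are implemented:

* **Humidex** — the Canadian (CCOHS) occupational index.  It adds to the dry
  air temperature a vapour-pressure excess term,

  .. math::

     \\mathrm{Humidex} = T + \\tfrac{5}{9}\\left(e - 10\\right), \\qquad
     e = 6.112 \\cdot 10^{7.5T/(237.7+T)} \\cdot \\tfrac{H}{100},

  with :math:`T` the air temperature in deg C, :math:`H` the relative humidity
  in percent, and :math:`e` the water-vapour pressure in hPa (Magnus form of
  the saturation pressure).  Humidex equals :math:`T` exactly when
  :math:`e = 10` hPa, and is reported in deg C equivalents.

* **Heat Index** — the US National Weather Service apparent temperature,
  evaluated as the 16-term full polynomial regression in temperature (deg F)
  and relative humidity (%).  Coefficients are data, not code: the canonical
  NWS coefficient vector is the default, and an alternate vector preserving a
  typeset variant of the equation (numerically unusable because of a
  misprinted exponent; see :data:`HEAT_INDEX_COEFFICIENTS_AS_PRINTED`) is
  retained for provenance.

All functions are pure, accept scalars or numpy arrays, and validate inputs
against the plausibility gates for indoor logger data instead of clipping.
Temperatures are handled in deg C everywhere; deg F appears only inside
``heat_index``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .errors import DomainError

__all__ = [
    "MeteoReading",
    "IndexValue",
    "humidex",
    "heat_index",
    "celsius_to_fahrenheit",
    "fahrenheit_to_celsius",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "dewpoint_to_rh",
    "rh_to_dewpoint",
    "HEAT_INDEX_COEFFICIENTS",
    "HEAT_INDEX_COEFFICIENTS_AS_PRINTED",
    "HeatIndexExtrapolationWarning",
]

# Magnus saturation-pressure constants; shared by Humidex and the dew-point
# conversions so the two moisture variables stay mutually consistent.
MAGNUS_BASE_HPA = 6.112
MAGNUS_A = 7.5
MAGNUS_B = 237.7

# Plausibility gates for indoor logger data; out of range is an error.
AIR_TEMP_MIN_C = -40.0
AIR_TEMP_MAX_C = 60.0

# Below this dry-bulb temperature the Heat Index regression extrapolates
# outside its hot-humid fitting domain.
HEAT_INDEX_VALID_MIN_F = 80.0


class HeatIndexExtrapolationWarning(UserWarning):
    """Heat Index evaluated outside the regression's hot-humid domain."""


def _as_array(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def _validate_air_temp(value) -> np.ndarray:
    arr = _as_array("air_temp", value)
    bad = (arr < AIR_TEMP_MIN_C) | (arr > AIR_TEMP_MAX_C)
    if np.any(bad):
        offending = float(np.atleast_1d(arr)[np.atleast_1d(bad)][0])
        raise DomainError(
            f"air_temp={offending} degC outside plausible range "
            f"[{AIR_TEMP_MIN_C}, {AIR_TEMP_MAX_C}]"
        )
    return arr


def _validate_rel_humidity(value) -> np.ndarray:
    arr = _as_array("rel_humidity", value)
    bad = (arr < 0.0) | (arr > 100.0)
    if np.any(bad):
        offending = float(np.atleast_1d(arr)[np.atleast_1d(bad)][0])
        raise DomainError(f"rel_humidity={offending} % outside range [0, 100]")
    return arr


def _scalar_like(result: np.ndarray, *inputs) -> float | np.ndarray:
    if all(np.isscalar(x) or np.ndim(x) == 0 for x in inputs):
        return float(result)
    return result


@dataclass(frozen=True)
class MeteoReading:
    """One timestamped logger observation.

    Parameters
    ----------
    timestamp : datetime
        Instant of the reading; must carry an explicit UTC offset.
    air_temp : float
        Air temperature in deg C, within [-40, 60].
    rel_humidity : float
        Relative humidity in percent, within [0, 100].
    dew_point : float, optional
        Dew-point temperature in deg C; must not exceed ``air_temp``.
    """

    timestamp: datetime
    air_temp: float
    rel_humidity: float
    dew_point: float | None = None

    def __post_init__(self):
        if self.timestamp.tzinfo is None or self.timestamp.utcoffset() is None:
            raise DomainError(
                f"timestamp={self.timestamp.isoformat()} lacks a UTC offset"
            )
        _validate_air_temp(self.air_temp)
        _validate_rel_humidity(self.rel_humidity)
        if self.dew_point is not None and self.dew_point > self.air_temp:
            raise DomainError(
                f"dew_point={self.dew_point} degC exceeds air_temp={self.air_temp} degC"
            )


@dataclass(frozen=True)
class IndexValue:
    """Computed apparent-temperature indices for one reading."""

    humidex: float
    heat_index_f: float
    heat_index_c: float


def celsius_to_fahrenheit(t):
    """Convert deg C to deg F."""
    arr = _as_array("temperature", t)
    return _scalar_like(arr * 9.0 / 5.0 + 32.0, t)


def fahrenheit_to_celsius(t):
    """Convert deg F to deg C."""
    arr = _as_array("temperature", t)
    return _scalar_like((arr - 32.0) * 5.0 / 9.0, t)


def saturation_vapour_pressure(air_temp):
    """Magnus-form saturation vapour pressure in hPa at ``air_temp`` deg C."""
    t = _validate_air_temp(air_temp)
    e_s = MAGNUS_BASE_HPA * 10.0 ** (MAGNUS_A * t / (MAGNUS_B + t))
    return _scalar_like(e_s, air_temp)


def vapour_pressure(air_temp, rel_humidity):
    """Actual water-vapour pressure in hPa from temperature and RH."""
    t = _validate_air_temp(air_temp)
    h = _validate_rel_humidity(rel_humidity)
    e = MAGNUS_BASE_HPA * 10.0 ** (MAGNUS_A * t / (MAGNUS_B + t)) * h / 100.0
    return _scalar_like(e, air_temp, rel_humidity)


def humidex(air_temp, rel_humidity):
    """Humidex in deg C equivalents from temperature (deg C) and RH (%).

    Strictly increasing in both arguments over the admissible input range;
    equals ``air_temp`` exactly at a vapour pressure of 10 hPa.
    """
    t = _validate_air_temp(air_temp)
    h = _validate_rel_humidity(rel_humidity)
    e = MAGNUS_BASE_HPA * 10.0 ** (MAGNUS_A * t / (MAGNUS_B + t)) * h / 100.0
    return _scalar_like(t + (5.0 / 9.0) * (e - 10.0), air_temp, rel_humidity)


# Canonical NWS 16-term full regression in T (deg F) and R (%), plus the
# closing +0.5 deg F constant.  Keys name the monomial each coefficient
# multiplies.
HEAT_INDEX_COEFFICIENTS: Mapping[str, float] = MappingProxyType({
    "const": 16.923,
    "T": 1.85212e-1,
    "R": 5.37941,
    "TR": -1.00254e-1,
    "T2": 9.41695e-3,
    "R2": 7.28898e-3,
    "T2R": 3.45372e-4,
    "TR2": -8.14971e-4,
    "T2R2": 1.02102e-5,
    "T3": -3.8646e-5,
    "R3": 2.91583e-5,
    "T3R": 1.42721e-6,
    "TR3": 1.97483e-7,
    "T3R2": -2.18429e-8,
    "T2R3": 8.43296e-10,
    "T3R3": -4.81975e-11,
    "offset": 0.5,
})

# A typeset variant of the same equation, preserved verbatim for provenance.
# It differs from the canonical vector in the constant (16.023 vs 16.923),
# the T2R2 coefficient (1.01202e-5, transposed digits) and, fatally, the T3R
# exponent (1.42721e+6 instead of 1e-6), which makes it numerically unusable.
HEAT_INDEX_COEFFICIENTS_AS_PRINTED: Mapping[str, float] = MappingProxyType({
    **dict(HEAT_INDEX_COEFFICIENTS),
    "const": 16.023,
    "T2": 9.4169e-3,
    "T2R2": 1.01202e-5,
    "T3R": 1.42721e6,
})

_MONOMIAL_POWERS = {
    "const": (0, 0), "T": (1, 0), "R": (0, 1), "TR": (1, 1),
    "T2": (2, 0), "R2": (0, 2), "T2R": (2, 1), "TR2": (1, 2),
    "T2R2": (2, 2), "T3": (3, 0), "R3": (0, 3), "T3R": (3, 1),
    "TR3": (1, 3), "T3R2": (3, 2), "T2R3": (2, 3), "T3R3": (3, 3),
}


def heat_index(air_temp, rel_humidity, *, coefficients: Mapping[str, float] | None = None):
    """NWS Heat Index from temperature (deg C) and relative humidity (%).

    The input temperature is converted to deg F internally, the 16-term
    polynomial is evaluated, and both the deg F output and its exact deg C
    re-conversion are returned.

    Parameters
    ----------
    air_temp, rel_humidity
        Scalars or arrays; deg C and percent.
    coefficients
        Optional replacement coefficient vector (same keys as
        :data:`HEAT_INDEX_COEFFICIENTS`).

    Returns
    -------
    (heat_index_f, heat_index_c)
        Apparent temperature in deg F and its deg C conversion.

    Warns
    -----
    HeatIndexExtrapolationWarning
        If any input lies below 80 deg F, where the regression extrapolates
        outside its hot-humid fitting domain.
    """
    t_c = _validate_air_temp(air_temp)
    r = _validate_rel_humidity(rel_humidity)
    coefs = dict(HEAT_INDEX_COEFFICIENTS if coefficients is None else coefficients)
    unknown = set(coefs) - set(_MONOMIAL_POWERS) - {"offset"}
    if unknown:
        raise DomainError(f"unknown heat-index coefficient keys: {sorted(unknown)}")

    t_f = t_c * 9.0 / 5.0 + 32.0
    if np.any(t_f < HEAT_INDEX_VALID_MIN_F):
        warnings.warn(
            "Heat Index evaluated below 80 degF; the regression is "
            "extrapolating outside its intended hot-humid domain",
            HeatIndexExtrapolationWarning,
            stacklevel=2,
        )

    hi_f = np.zeros(np.broadcast(t_f, r).shape)
    for key, coef in coefs.items():
        if key == "offset":
            hi_f = hi_f + coef
        else:
            p, q = _MONOMIAL_POWERS[key]
            hi_f = hi_f + coef * t_f**p * r**q
    hi_c = (hi_f - 32.0) * 5.0 / 9.0
    return (
        _scalar_like(hi_f, air_temp, rel_humidity),
        _scalar_like(hi_c, air_temp, rel_humidity),
    )


def dewpoint_to_rh(air_temp, dew_point):
    """Relative humidity (%) from air and dew-point temperature (deg C).

    Magnus saturation-pressure ratio with the same constants as the Humidex
    vapour-pressure term, so either moisture variable can drive the pipeline
    consistently.  Result lies in (0, 100].
    """
    t = _validate_air_temp(air_temp)
    td = _as_array("dew_point", dew_point)
    if np.any(td > t):
        raise DomainError(
            f"dew_point={float(np.max(td))} degC exceeds air_temp; "
            "dew point cannot be warmer than the air"
        )
    ratio = 10.0 ** (MAGNUS_A * td / (MAGNUS_B + td) - MAGNUS_A * t / (MAGNUS_B + t))
    return _scalar_like(100.0 * ratio, air_temp, dew_point)


def rh_to_dewpoint(air_temp, rel_humidity):
    """Dew-point temperature (deg C) from air temperature and RH (%).

    Inverse of :func:`dewpoint_to_rh`; requires strictly positive humidity.
    """
    t = _validate_air_temp(air_temp)
    h = _validate_rel_humidity(rel_humidity)
    if np.any(h <= 0.0):
        raise DomainError("rel_humidity=0 %: dew point undefined for dry air")
    # e = 6.112 * 10**(a t/(b+t)) * h/100 ; invert the Magnus form for Td.
    log_e = np.log10(h / 100.0) + MAGNUS_A * t / (MAGNUS_B + t)
    td = MAGNUS_B * log_e / (MAGNUS_A - log_e)
    return _scalar_like(td, air_temp, rel_humidity)


def compute_indices(air_temp, rel_humidity, *, coefficients: Mapping[str, float] | None = None):
    """Evaluate all indices at once; returns dict of arrays/scalars."""
    hx = humidex(air_temp, rel_humidity)
    hi_f, hi_c = heat_index(air_temp, rel_humidity, coefficients=coefficients)
    return {"humidex_c": hx, "heat_index_f": hi_f, "heat_index_c": hi_c}
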