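"""Heat-attributable excess mortality from daily weather via exposure-response
functions (ERFs).

A city's ERF is a log-linear relation between daily all-cause mortality and
maximum daily apparent temperature (AT_max) above a city-specific threshold.
Daily attributable deaths follow the relative-risk identity

    D_attr = D_obs * (1 - exp(-b * dAT_max)),    dAT_max = max(0, AT3 - threshold)

where D_obs is the observed average daily mortality in the warm season, b the
log-linear slope per degree C, and AT3 the trailing 3-day mean of AT_max
(lag effects).  Attributable deaths are summed over all threshold-exceedance
days in the analysis period and reported per 100,000 of the city population.

Apparent temperature combines the daily maximum temperature with a humidity
term through the dew point,

    AT_max = -2.653 + 0.994 * T_max + 0.0153 * Td^2,

with the dew point Td obtained by inverting Tetens' saturation vapor pressure
formula at the daily mean temperature and relative humidity.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingDataError

# Tetens constants (water surface branch), saturation vapor pressure in hPa.
TETENS_E0 = 6.1078
TETENS_A = 7.5
TETENS_B = 237.3

# Apparent-temperature regression coefficients (deg C in, deg C out).
AT_INTERCEPT = -2.653
AT_TMAX_COEF = 0.994
AT_DEW_COEF = 0.0153

WEATHER_COLUMNS = ("date", "t_mean", "t_max", "rh")

DateLike = Union[str, _dt.date, pd.Timestamp]


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One day of mean/max temperature (deg C) and relative humidity (%)."""

    date: pd.Timestamp
    t_mean: float
    t_max: float
    rh: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        if self.t_max < self.t_mean:
            raise InvalidInputError(
                f"{self.date.date()}: t_max ({self.t_max}) < t_mean ({self.t_mean})"
            )
        if not 0.0 <= self.rh <= 100.0:
            raise InvalidInputError(f"{self.date.date()}: rh must be in [0, 100]")


def validate_weather_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a daily weather table (sorted, typed)."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"weather table missing columns {missing}")
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    if out["date"].duplicated().any():
        raise InvalidInputError("duplicate dates in weather table")
    out = out.sort_values("date").reset_index(drop=True)
    for col in ("t_mean", "t_max", "rh"):
        out[col] = pd.to_numeric(out[col])
        if not np.all(np.isfinite(out[col])):
            raise InvalidInputError(f"non-finite values in weather column {col!r}")
    if (out["t_max"] < out["t_mean"]).any():
        raise InvalidInputError("t_max < t_mean on some days")
    if ((out["rh"] < 0) | (out["rh"] > 100)).any():
        raise InvalidInputError("relative humidity outside [0, 100]")
    return out


@dataclass(frozen=True)
class ExposureResponse:
    """A city's temperature-mortality exposure-response function.

    Slopes are log-linear per degree C (``b``), with the central estimate
    bracketed by the 95% confidence interval.  Use
    :meth:`from_percent_slopes` to convert published "% change in daily
    mortality per degree" values.
    """

    city: str
    threshold_at: float
    slope_central: float
    slope_lo: float
    slope_hi: float
    baseline_daily_deaths: float
    population: float

    def __post_init__(self) -> None:
        if not self.slope_lo <= self.slope_central <= self.slope_hi:
            raise InvalidInputError(
                f"{self.city}: slope CI must be ordered lo <= central <= hi"
            )
        if self.baseline_daily_deaths < 0:
            raise InvalidInputError(f"{self.city}: baseline deaths must be >= 0")
        if self.population <= 0:
            raise InvalidInputError(f"{self.city}: population must be > 0")

    @classmethod
    def from_percent_slopes(
        cls,
        city: str,
        threshold_at: float,
        pct_central: float,
        pct_lo: float,
        pct_hi: float,
        baseline_daily_deaths: float,
        population: float,
        convention: str = "log",
    ) -> "ExposureResponse":
        """Build from percentage-change slopes.

        ``convention="log"`` uses the exact log-linear conversion
        b = ln(1 + p/100); ``"linear"`` uses the first-order b = p/100.
        """
        conv = {"log": lambda p: float(np.log1p(p / 100.0)),
                "linear": lambda p: p / 100.0}
        if convention not in conv:
            raise InvalidInputError(f"unknown slope convention {convention!r}")
        f = conv[convention]
        return cls(
            city=city,
            threshold_at=threshold_at,
            slope_central=f(pct_central),
            slope_lo=f(pct_lo),
            slope_hi=f(pct_hi),
            baseline_daily_deaths=baseline_daily_deaths,
            population=population,
        )


@dataclass(frozen=True)
class MortalityEstimate:
    """Total attributable excess deaths with CI, plus per-100,000 rates."""

    city: str
    deaths_central: float
    deaths_lo: float
    deaths_hi: float
    rate_central: float
    rate_lo: float
    rate_hi: float
    n_exceedance_days: int
    period: Tuple[pd.Timestamp, pd.Timestamp]

    def to_dict(self) -> dict:
        return {
            "city": self.city,
            "deaths_central": self.deaths_central,
            "deaths_lo": self.deaths_lo,
            "deaths_hi": self.deaths_hi,
            "rate_per_100k_central": self.rate_central,
            "rate_per_100k_lo": self.rate_lo,
            "rate_per_100k_hi": self.rate_hi,
            "n_exceedance_days": self.n_exceedance_days,
            "period_start": str(self.period[0].date()),
            "period_end": str(self.period[1].date()),
        }


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------


def tetens_saturation_vp(t):
    """Saturation vapor pressure (hPa) at temperature t (deg C), Tetens form.

    e_s(t) = 6.1078 * 10^(7.5 t / (t + 237.3)); strictly increasing in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= -TETENS_B):
        raise InvalidInputError(f"temperature must exceed {-TETENS_B} deg C")
    out = TETENS_E0 * 10.0 ** (TETENS_A * t / (t + TETENS_B))
    return float(out) if out.ndim == 0 else out


def dew_point(t_mean, rh):
    """Dew point (deg C) from mean temperature and relative humidity.

    Inverts Tetens at the actual vapor pressure e = (rh/100) e_s(t_mean);
    Td <= t_mean with equality at saturation.
    """
    t_mean = np.asarray(t_mean, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise InvalidInputError("relative humidity must be in (0, 100]")
    e = (rh / 100.0) * tetens_saturation_vp(t_mean)
    x = np.log10(e / TETENS_E0)
    out = TETENS_B * x / (TETENS_A - x)
    return float(out) if out.ndim == 0 else out


def apparent_temperature_max(t_mean, t_max, rh):
    """Maximum daily apparent temperature (deg C).

    Combines the daily maximum temperature with a quadratic dew-point term,
    the dew point taken from the daily mean temperature and relative
    humidity.  Strictly increasing in t_max, and in rh at fixed temperatures.
    """
    t_mean = np.asarray(t_mean, dtype=float)
    t_max = np.asarray(t_max, dtype=float)
    if np.any(t_max < t_mean):
        raise InvalidInputError("t_max < t_mean")
    td = dew_point(t_mean, rh)
    out = AT_INTERCEPT + AT_TMAX_COEF * t_max + AT_DEW_COEF * np.square(td)
    return float(out) if np.ndim(out) == 0 else out


def rolling_3day(values) -> np.ndarray:
    """Trailing 3-day mean (days t-2, t-1, t), window shrinking at the start.

    Trailing (not centred) so that today's heat burden reflects today and the
    two preceding days only - lag effects cannot be anticipatory.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty series")
    return pd.Series(values).rolling(3, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# Attributable mortality
# ---------------------------------------------------------------------------


def _period_slice(weather: pd.DataFrame, period: Tuple[DateLike, DateLike]):
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if start > end:
        raise InvalidInputError("period start after end")
    dates = weather["date"]
    if start < dates.iloc[0] or end > dates.iloc[-1]:
        raise MissingDataError(
            f"period {start.date()}..{end.date()} outside weather coverage "
            f"{dates.iloc[0].date()}..{dates.iloc[-1].date()}"
        )
    sel = (dates >= start) & (dates <= end)
    n_expected = (end - start).days + 1
    if int(sel.sum()) != n_expected:
        raise MissingDataError("weather table has missing days inside the period")
    return sel.to_numpy(), (start, end)


def attributable_deaths(
    erf: ExposureResponse,
    weather: pd.DataFrame,
    period: Tuple[DateLike, DateLike],
    slope: str = "central",
) -> Tuple[float, int]:
    """Total attributable deaths and exceedance-day count over a period.

    The 3-day smoothing of AT_max is computed over the full weather table
    (so days just before the period contribute lag), and both the threshold
    test and the exceedance magnitude use the smoothed series.  A negative
    lower-CI slope is clamped to zero with a warning (cold effects are out of
    scope of the heat ERF).
    """
    if slope not in ("central", "lo", "hi"):
        raise InvalidInputError(f"slope must be central|lo|hi, got {slope!r}")
    weather = validate_weather_frame(weather)
    sel, _ = _period_slice(weather, period)
    b = getattr(erf, f"slope_{slope}" if slope != "central" else "slope_central")
    if b < 0:
        warnings.warn(
            f"{erf.city}: negative {slope} slope {b:.4g} clamped to 0",
            stacklevel=2,
        )
        b = 0.0
    at = apparent_temperature_max(
        weather["t_mean"].to_numpy(), weather["t_max"].to_numpy(), weather["rh"].to_numpy()
    )
    at3 = rolling_3day(at)
    delta = np.clip(at3 - erf.threshold_at, 0.0, None)[sel]
    daily = erf.baseline_daily_deaths * (1.0 - np.exp(-b * delta))
    return float(daily.sum()), int((delta > 0).sum())


def per_capita_rate(deaths: float, population: float) -> float:
    """Deaths per 100,000 of the population."""
    if population <= 0:
        raise InvalidInputError("population must be > 0")
    return deaths / population * 1e5


def estimate_mortality(
    erf: ExposureResponse,
    weather: pd.DataFrame,
    period: Tuple[DateLike, DateLike],
) -> MortalityEstimate:
    """Central and 95%-CI attributable mortality for one city and period."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lo-slope clamp already documented
        lo, _ = attributable_deaths(erf, weather, period, "lo")
    central, n_exc = attributable_deaths(erf, weather, period, "central")
    hi, _ = attributable_deaths(erf, weather, period, "hi")
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    return MortalityEstimate(
        city=erf.city,
        deaths_central=central,
        deaths_lo=lo,
        deaths_hi=hi,
        rate_central=per_capita_rate(central, erf.population),
        rate_lo=per_capita_rate(lo, erf.population),
        rate_hi=per_capita_rate(hi, erf.population),
        n_exceedance_days=n_exc,
        period=(start, end),
    )
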