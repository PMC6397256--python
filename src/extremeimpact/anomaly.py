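"""Trend-adjusted standardized event anomalies for annual indicator series.

The common impact metric used across sectors: an indicator's deviation in the
event year from the detrended historical mean, expressed in units of the
historical standard deviation of the detrended residuals, with the event year
excluded from the standard deviation so that the event itself does not
inflate the yardstick it is measured against.

Three detrending conventions are supported, matching how different sectors
treat long-term change in their indicator:

``linear``
    Ordinary least-squares line over the full series (river discharge,
    ecosystem productivity).
``moving_average``
    Centred moving average, default 7-year window, with the window shrunk
    symmetrically at the series edges so the output keeps the input length
    (crop yields, where technology trends are non-linear).
``constant``
    Subtraction of the series mean (hydropower, where no substantial trend
    exists).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateVarianceError, InvalidInputError, MissingDataError

DETREND_METHODS = ("linear", "moving_average", "constant")

#: Minimum series length for a standardized anomaly.
MIN_ANOMALY_YEARS = 5
#: Minimum number of non-event residuals entering the standard deviation.
MIN_SIGMA_YEARS = 3


@dataclass(frozen=True)
class AnnualSeries:
    """A year-indexed numeric indicator series.

    Parameters
    ----------
    years : array-like of int
        Calendar years, strictly increasing.  Gaps (missing years) are an
        error unless ``allow_gaps=True``.
    values : array-like of float
        One finite value per year.
    units : str
        Free-text unit label carried through to results.
    allow_gaps : bool
        Explicitly flag a series with missing years as acceptable.
    """

    years: np.ndarray
    values: np.ndarray
    units: str = ""
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        years = np.atleast_1d(np.asarray(self.years))
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if years.ndim != 1 or values.ndim != 1:
            raise InvalidInputError("years and values must be one-dimensional")
        if len(years) != len(values):
            raise InvalidInputError(
                f"length mismatch: {len(years)} years vs {len(values)} values"
            )
        if len(years) == 0:
            raise InvalidInputError("empty series")
        if not np.issubdtype(years.dtype, np.integer):
            as_int = years.astype(int)
            if not np.array_equal(as_int, years.astype(float)):
                raise InvalidInputError("years must be integers")
            years = as_int
        diffs = np.diff(years)
        if np.any(diffs <= 0):
            raise InvalidInputError("years must be strictly increasing")
        if not self.allow_gaps and np.any(diffs != 1):
            missing = [
                int(y)
                for y in range(int(years[0]), int(years[-1]) + 1)
                if y not in set(years.tolist())
            ]
            raise MissingDataError(
                f"series has missing years {missing}; pass allow_gaps=True to accept"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must all be finite")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.years)

    def index_of(self, year: int) -> int:
        idx = np.flatnonzero(self.years == int(year))
        if len(idx) == 0:
            raise InvalidInputError(f"year {year} not in series")
        return int(idx[0])

    def value_at(self, year: int) -> float:
        return float(self.values[self.index_of(year)])

    def with_values(self, values: np.ndarray) -> "AnnualSeries":
        """Same year axis and metadata, new values."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class DetrendSpec:
    """How long-term change is removed before the anomaly is computed."""

    method: str = "linear"
    window: int = 7

    def __post_init__(self) -> None:
        if self.method not in DETREND_METHODS:
            raise InvalidInputError(
                f"unknown detrend method {self.method!r}; choose from {DETREND_METHODS}"
            )
        if self.method == "moving_average":
            if int(self.window) != self.window or self.window < 3 or self.window % 2 == 0:
                raise InvalidInputError(
                    f"moving-average window must be an odd integer >= 3, got {self.window}"
                )


@dataclass(frozen=True)
class AnomalyResult:
    """A standardized event anomaly with full provenance.

    ``anomaly_sigma = raw_deviation / sigma_value`` where ``raw_deviation``
    is the detrended residual in the event year (native units) and
    ``sigma_value`` the sample standard deviation (n-1 denominator) of the
    detrended residuals inside ``sigma_years``, event year excluded.
    """

    anomaly_sigma: float
    event_year: int
    detrend: DetrendSpec
    sigma_years: Tuple[int, int]
    sigma_value: float
    raw_deviation: float
    n_sigma_years: int
    units: str = ""
    fit_excludes_event: bool = False

    def to_dict(self) -> dict:
        return {
            "anomaly_sigma": self.anomaly_sigma,
            "event_year": self.event_year,
            "detrend_method": self.detrend.method,
            "detrend_window": self.detrend.window
            if self.detrend.method == "moving_average"
            else "",
            "sigma_start": self.sigma_years[0],
            "sigma_end": self.sigma_years[1],
            "sigma_value": self.sigma_value,
            "raw_deviation": self.raw_deviation,
            "n_sigma_years": self.n_sigma_years,
            "units": self.units,
            "fit_excludes_event": self.fit_excludes_event,
        }


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------


def detrend_linear(series: AnnualSeries) -> Tuple[AnnualSeries, float, float]:
    """Remove an ordinary least-squares linear trend fitted over all years.

    Returns the residual series plus ``(slope, intercept)``.  Residuals sum
    to zero (OLS with intercept).
    """
    if len(series) < 3:
        raise InvalidInputError("linear detrend needs at least 3 years")
    slope, intercept = np.polyfit(series.years.astype(float), series.values, 1)
    residuals = series.values - (intercept + slope * series.years)
    return series.with_values(residuals), float(slope), float(intercept)


def _shrunk_window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Centred windowed means; half-width shrinks symmetrically at the edges.

    At index i the half-width is ``min((window-1)//2, i, n-1-i)``, so the
    window is always symmetric about i and the output has the input length.
    A symmetric window reproduces any exactly linear series.
    """
    n = len(values)
    h_max = (window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for i in range(n):
        h = min(h_max, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def detrend_moving_average(series: AnnualSeries, window: int = 7) -> AnnualSeries:
    """Remove a centred moving average with edge-shrunk windows."""
    DetrendSpec("moving_average", window)  # validates the window
    means = _shrunk_window_means(series.values, int(window))
    return series.with_values(series.values - means)


def detrend_constant(series: AnnualSeries) -> AnnualSeries:
    """Remove the series mean (for indicators with no substantial trend)."""
    return series.with_values(series.values - series.values.mean())


def detrend(series: AnnualSeries, spec: DetrendSpec) -> AnnualSeries:
    """Dispatch on :class:`DetrendSpec`; returns the residual series."""
    if spec.method == "linear":
        return detrend_linear(series)[0]
    if spec.method == "moving_average":
        return detrend_moving_average(series, spec.window)
    return detrend_constant(series)


def _anomaly_residuals(
    series: AnnualSeries,
    spec: DetrendSpec,
    event_year: int,
    fit_excludes_event: bool,
) -> np.ndarray:
    """Residuals over the full series under the requested fit convention.

    By default the linear/constant fit includes the event year (the most
    literal reading of subtracting "a linear trend" / "a constant mean" from
    the full series).  With ``fit_excludes_event=True`` the fit is estimated
    on the non-event years only, residuals still evaluated at every year.
    The flag does not apply to the moving-average method, whose local window
    means always use the values present.
    """
    if not fit_excludes_event or spec.method == "moving_average":
        return detrend(series, spec).values
    e = series.index_of(event_year)
    mask = np.ones(len(series), dtype=bool)
    mask[e] = False
    yrs = series.years.astype(float)
    if spec.method == "linear":
        if mask.sum() < 3:
            raise InvalidInputError("linear detrend needs at least 3 non-event years")
        slope, intercept = np.polyfit(yrs[mask], series.values[mask], 1)
        return series.values - (intercept + slope * yrs)
    return series.values - series.values[mask].mean()


def standardized_anomaly(
    series: AnnualSeries,
    event_year: int,
    detrend_spec: DetrendSpec = DetrendSpec("linear"),
    sigma_years: Optional[Tuple[int, int]] = None,
    fit_excludes_event: bool = False,
) -> AnomalyResult:
    """Standardized anomaly of ``event_year`` relative to the rest of the series.

    Procedure: (1) detrend the full series per ``detrend_spec``; (2) the raw
    deviation is the residual in the event year; (3) the standard deviation
    is the sample (n-1) standard deviation of the residuals inside
    ``sigma_years`` (inclusive range; default the full series) with the
    event year excluded; (4) the anomaly is the ratio of the two.

    A short sigma window supports indicators whose observational record is
    shorter than the simulation period (the trend is still fitted over the
    full series).
    """
    if len(series) < MIN_ANOMALY_YEARS:
        raise InvalidInputError(
            f"anomaly needs at least {MIN_ANOMALY_YEARS} years, got {len(series)}"
        )
    e = series.index_of(event_year)
    residuals = _anomaly_residuals(series, detrend_spec, event_year, fit_excludes_event)
    raw = float(residuals[e])

    if sigma_years is None:
        lo, hi = int(series.years[0]), int(series.years[-1])
    else:
        lo, hi = int(sigma_years[0]), int(sigma_years[1])
        if lo > hi:
            raise InvalidInputError("sigma_years range is reversed")
    mask = (series.years >= lo) & (series.years <= hi)
    mask[e] = False
    n_sigma = int(mask.sum())
    if n_sigma < MIN_SIGMA_YEARS:
        raise InvalidInputError(
            f"need at least {MIN_SIGMA_YEARS} non-event years in the sigma window, "
            f"got {n_sigma}"
        )
    sigma = float(np.std(residuals[mask], ddof=1))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateVarianceError(
            "residuals are constant outside the event year; anomaly undefined"
        )
    return AnomalyResult(
        anomaly_sigma=raw / sigma,
        event_year=int(event_year),
        detrend=detrend_spec,
        sigma_years=(lo, hi),
        sigma_value=sigma,
        raw_deviation=raw,
        n_sigma_years=n_sigma,
        units=series.units,
        fit_excludes_event=fit_excludes_event,
    )


# ---------------------------------------------------------------------------
# Monthly extraction
# ---------------------------------------------------------------------------


def extract_month(
    values: pd.Series,
    month: int,
    units: str = "",
    allow_missing: bool = False,
) -> AnnualSeries:
    """Annual series of a single month's mean from a dated series.

    ``values`` is a pandas Series indexed by datetime (daily or monthly
    resolution).  Each year contributes the mean of its values falling in
    ``month``.  Years inside the covered span with no data for that month are
    an error unless ``allow_missing=True``, in which case they are dropped
    and the result is flagged as gappy.
    """
    if not 1 <= int(month) <= 12:
        raise InvalidInputError(f"month must be in 1..12, got {month}")
    if not isinstance(values.index, pd.DatetimeIndex):
        raise InvalidInputError("extract_month needs a DatetimeIndex")
    if len(values) == 0:
        raise InvalidInputError("empty input series")
    sel = values[values.index.month == int(month)]
    if len(sel) == 0:
        raise MissingDataError(f"no data for month {month}")
    by_year = sel.groupby(sel.index.year).mean()
    span = range(int(values.index.year.min()), int(values.index.year.max()) + 1)
    missing = [y for y in span if y not in by_year.index]
    if missing and not allow_missing:
        raise MissingDataError(
            f"month {month} missing in years {missing}; pass allow_missing=True"
        )
    return AnnualSeries(
        years=by_year.index.to_numpy(),
        values=by_year.to_numpy(),
        units=units,
        allow_gaps=bool(missing),
    )
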