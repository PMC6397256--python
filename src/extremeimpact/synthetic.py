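"""Synthetic inputs with the statistical structure the analysis assumes.

Annual indicator series are modelled as a linear trend plus Gaussian
interannual noise, with a single additive event-year shock of known magnitude
expressed in units of the true interannual standard deviation.  Multi-model
ensembles replicate the observed structure with a per-model attenuation of
the shock (factors above 1 amplify it, emulating models that over-react) and
their own noise.  Daily weather is a sinusoidal seasonal cycle plus noise,
with a heat-wave window in which temperatures are raised by a fixed
amplitude.  Gridded crop yields carry the event shock fully in the rainfed
component and attenuated in the irrigated one, with interannual variability
shared across a country's cells (country-scale weather) plus smaller
cell-level noise.

Noiseless mode
--------------
With ``noise_sd = 0`` the standardized anomaly would be a 0/0 limit, so the
generators switch to an exact deterministic construction: a fixed
pseudo-random interannual pattern (reproducible from the seed) is combined
with an event increment solved numerically so that the standardized anomaly
of the generated series equals the designed magnitude *exactly* under the
requested detrend.  This gives ground-truth series for which the full
pipeline must recover the designed classification with certainty.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .anomaly import AnnualSeries, DetrendSpec, _shrunk_window_means
from .errors import InvalidInputError
from .sectors import GridCellYield


# ---------------------------------------------------------------------------
# Residual projection operators (for the exact construction)
# ---------------------------------------------------------------------------


def residual_operator(years: np.ndarray, spec: DetrendSpec) -> np.ndarray:
    """Matrix R such that detrended residuals = R @ values.

    All three detrend methods are linear in the input, so each has an exact
    matrix representation: I - H for the OLS hat matrix (linear), I - J/n
    (constant), I - M for the edge-shrunk windowed-mean matrix
    (moving_average).
    """
    years = np.asarray(years, dtype=float)
    n = len(years)
    eye = np.eye(n)
    if spec.method == "linear":
        x = np.column_stack([np.ones(n), years])
        hat = x @ np.linalg.solve(x.T @ x, x.T)
        return eye - hat
    if spec.method == "constant":
        return eye - np.full((n, n), 1.0 / n)
    m = np.array([_shrunk_window_means(eye[:, j], spec.window) for j in range(n)]).T
    return eye - m


def _pattern_anomaly(r_op: np.ndarray, pattern: np.ndarray, event_idx: int) -> float:
    """Standardized anomaly of a residual pattern (matrix route)."""
    resid = r_op @ pattern
    others = np.delete(resid, event_idx)
    sd = others.std(ddof=1)
    if sd == 0:
        raise InvalidInputError("degenerate base pattern")
    return float(resid[event_idx] / sd)


def exact_event_pattern(
    n_years: int,
    event_idx: int,
    k: float,
    spec: DetrendSpec,
    rng: np.random.Generator,
    years: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Zero-trend pattern whose standardized anomaly is exactly ``k``.

    A pseudo-random base pattern u is combined with an event-year increment
    beta, with beta solved by root finding so that the detrended residual at
    the event divided by the non-event residual standard deviation equals k.
    The returned pattern has unit non-event residual standard deviation.
    """
    if years is None:
        years = np.arange(n_years, dtype=float)
    r_op = residual_operator(years, spec)
    delta = np.zeros(n_years)
    delta[event_idx] = 1.0
    u = rng.standard_normal(n_years)

    def f(beta: float) -> float:
        return _pattern_anomaly(r_op, u + beta * delta, event_idx) - k

    lo, hi = -1.0, 1.0
    for _ in range(60):
        if f(lo) < 0 < f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise InvalidInputError(
            f"designed anomaly {k} is outside the achievable range for this "
            f"series length and detrend"
        )
    beta = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    pattern = u + beta * delta
    resid = r_op @ pattern
    sd = np.delete(resid, event_idx).std(ddof=1)
    return pattern / sd


# ---------------------------------------------------------------------------
# Annual multi-model ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleScenario:
    """Design of one observed + multi-model annual-series experiment.

    ``event_magnitude_sigma`` is the true event anomaly in units of the
    interannual standard deviation; ``attenuation`` holds one non-negative
    factor per model (1 = faithful, < 1 = damped, > 1 = amplified).  With
    ``noise_sd = 0`` the exact deterministic construction is used and
    ``sigma_scale`` sets the magnitude of the deterministic interannual
    pattern in native units.
    """

    n_years: int = 30
    start_year: int = 1979
    event_year: int = 2003
    intercept: float = 100.0
    trend_slope: float = 0.0
    noise_sd: float = 1.0
    event_magnitude_sigma: float = -3.0
    n_models: int = 5
    attenuation: Optional[Tuple[float, ...]] = None
    model_noise_sd: Optional[float] = None
    sigma_scale: float = 1.0
    detrend: DetrendSpec = field(default_factory=DetrendSpec)
    units: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise InvalidInputError("n_years must be >= 10")
        if not self.start_year <= self.event_year < self.start_year + self.n_years:
            raise InvalidInputError("event_year outside the series range")
        if self.noise_sd < 0 or self.sigma_scale <= 0:
            raise InvalidInputError("noise_sd must be >= 0 and sigma_scale > 0")
        att = self.attenuation
        if att is None:
            att = tuple(1.0 for _ in range(self.n_models))
        att = tuple(float(a) for a in att)
        if len(att) != self.n_models:
            raise InvalidInputError("attenuation length must equal n_models")
        if any(a < 0 for a in att):
            raise InvalidInputError("attenuation factors must be >= 0")
        object.__setattr__(self, "attenuation", att)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def event_idx(self) -> int:
        return self.event_year - self.start_year


@dataclass(frozen=True)
class EnsembleGroundTruth:
    """Design values returned alongside generated ensembles."""

    event_magnitude_sigma: float
    attenuation: Tuple[float, ...]
    noise_sd: float
    event_year: int


def gen_annual_ensemble(
    scn: EnsembleScenario,
) -> Tuple[AnnualSeries, List[AnnualSeries], EnsembleGroundTruth]:
    """Observed series, model ensemble, and the ground truth that built them."""
    rng = np.random.default_rng(scn.seed)
    years = scn.years
    t = years - scn.start_year
    base = scn.intercept + scn.trend_slope * t
    e = scn.event_idx
    k = scn.event_magnitude_sigma
    exact = scn.noise_sd == 0

    def one(k_eff: float, noise_sd: float) -> AnnualSeries:
        if exact:
            pattern = exact_event_pattern(
                scn.n_years, e, k_eff, scn.detrend, rng, years=years.astype(float)
            )
            values = base + scn.sigma_scale * pattern
        else:
            values = base + rng.normal(0.0, noise_sd, scn.n_years)
            # shock in units of the *observed* interannual sd (the true sigma)
            values[e] += k_eff * scn.noise_sd
        return AnnualSeries(years, values, units=scn.units)

    observed = one(k, scn.noise_sd)
    model_sd = scn.noise_sd if scn.model_noise_sd is None else scn.model_noise_sd
    models = [one(a * k, model_sd) for a in scn.attenuation]
    truth = EnsembleGroundTruth(
        event_magnitude_sigma=k,
        attenuation=scn.attenuation,
        noise_sd=scn.noise_sd,
        event_year=scn.event_year,
    )
    return observed, models, truth


# ---------------------------------------------------------------------------
# Daily weather
# ---------------------------------------------------------------------------

DateLike = Union[str, _dt.date, pd.Timestamp]


@dataclass(frozen=True)
class WeatherScenario:
    """Design of a synthetic daily weather table with an injected heat wave.

    Mean temperature follows a sinusoidal seasonal cycle (peak near
    mid-July) plus Gaussian noise; the daily maximum sits half a diurnal
    range above the mean; inside the heat-wave window both are raised by
    ``heatwave_amplitude``.  Humidity is Gaussian around ``rh_mean`` with a
    drop inside the window (hot spells are dry), clipped to [5, 100].
    """

    start: DateLike = "2003-05-15"
    end: DateLike = "2003-08-31"
    t_base: float = 11.0
    seasonal_amplitude: float = 9.0
    peak_doy: int = 197
    diurnal_range: float = 8.0
    heatwave_start: DateLike = "2003-08-01"
    heatwave_end: DateLike = "2003-08-14"
    heatwave_amplitude: float = 8.0
    rh_mean: float = 60.0
    rh_heatwave_drop: float = 15.0
    rh_sd: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        hws, hwe = pd.Timestamp(self.heatwave_start), pd.Timestamp(self.heatwave_end)
        if start > end:
            raise InvalidInputError("weather period start after end")
        if hws > hwe or hws < start or hwe > end:
            raise InvalidInputError("heat-wave window must lie inside the period")
        if self.heatwave_amplitude < 0:
            raise InvalidInputError("heat-wave amplitude must be >= 0")
        if self.noise_sd < 0 or self.rh_sd < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")


def gen_daily_weather(scn: WeatherScenario) -> pd.DataFrame:
    """Daily weather table with columns date, t_mean, t_max, rh."""
    rng = np.random.default_rng(scn.seed)
    dates = pd.date_range(scn.start, scn.end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    in_hw = (dates >= pd.Timestamp(scn.heatwave_start)) & (
        dates <= pd.Timestamp(scn.heatwave_end)
    )
    seasonal = scn.t_base + scn.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - scn.peak_doy) / 365.25
    )
    t_mean = seasonal + scn.heatwave_amplitude * in_hw + rng.normal(
        0.0, scn.noise_sd, len(dates)
    )
    spread = np.clip(
        scn.diurnal_range / 2.0 + rng.normal(0.0, scn.noise_sd / 2.0, len(dates)),
        0.0,
        None,
    )
    t_max = t_mean + spread
    rh = np.clip(
        scn.rh_mean
        - scn.rh_heatwave_drop * in_hw
        + rng.normal(0.0, scn.rh_sd, len(dates)),
        5.0,
        100.0,
    )
    return pd.DataFrame(
        {"date": dates, "t_mean": t_mean, "t_max": t_max, "rh": rh}
    )


# ---------------------------------------------------------------------------
# Gridded crop yields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridYieldGroundTruth:
    """Designed country-level anomaly implied by the per-regime shocks."""

    country_shock_sigma: float
    shock_rainfed_sigma: float
    shock_irrigated_sigma: float


def _weighted_country_shock(
    frac_irrigated: np.ndarray,
    areas: np.ndarray,
    shock_rainfed: float,
    shock_irrigated: float,
) -> float:
    f_irr = frac_irrigated
    f_rf = 1.0 - frac_irrigated
    combined = f_irr * shock_irrigated + f_rf * shock_rainfed  # f_irr + f_rf = 1
    return float(np.average(combined, weights=areas))


def gen_grid_yields(
    n_cells: int,
    years: Sequence[int],
    event_year: int,
    shock_rainfed_sigma: float,
    shock_irrigated_sigma: float = 0.0,
    *,
    frac_irrigated: Union[float, Sequence[float], None] = None,
    harvested_area: Union[float, Sequence[float]] = 1000.0,
    base_yield_rainfed: float = 5.0,
    base_yield_irrigated: float = 7.5,
    trend_slope: float = 0.0,
    sigma_scale: float = 0.4,
    noise_sd: float = 0.0,
    cell_noise_sd: float = 0.0,
    detrend: DetrendSpec = DetrendSpec("moving_average", 7),
    seed: int = 0,
) -> Tuple[List[GridCellYield], GridYieldGroundTruth]:
    """Grid-cell yield records for one country, with known ground truth.

    The event-year shock (in sigma units) hits the rainfed component fully
    and the irrigated component by ``shock_irrigated_sigma`` (typically
    attenuated: irrigation buffers drought).  Interannual variability is a
    country-scale pattern shared by all cells (scaled by ``sigma_scale``
    t/ha), plus optional independent cell noise.  With ``noise_sd = 0`` the
    shared pattern is the exact construction, so the harvested-area-weighted
    country anomaly equals the weighted per-regime shock exactly under
    ``detrend``; with noise it does so in expectation.
    """
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    years = np.asarray(list(years), dtype=int)
    n_years = len(years)
    rng = np.random.default_rng(seed)
    if frac_irrigated is None:
        f_irr = rng.uniform(0.0, 1.0, n_cells)
    else:
        f_irr = np.broadcast_to(np.asarray(frac_irrigated, dtype=float), (n_cells,)).copy()
    if np.any((f_irr < 0) | (f_irr > 1)):
        raise InvalidInputError("frac_irrigated must be in [0, 1]")
    areas = np.broadcast_to(np.asarray(harvested_area, dtype=float), (n_cells,)).copy()

    e = int(np.flatnonzero(years == int(event_year))[0]) if event_year in years else None
    if e is None:
        raise InvalidInputError("event_year not in years")

    k_country = _weighted_country_shock(
        f_irr, areas, shock_rainfed_sigma, shock_irrigated_sigma
    )
    t = years - years[0]
    if noise_sd == 0:
        if k_country == 0.0:
            pattern = exact_event_pattern(n_years, e, 1e-12, detrend, rng,
                                          years=years.astype(float))
        else:
            pattern = exact_event_pattern(n_years, e, k_country, detrend, rng,
                                          years=years.astype(float))
        # remove the solved event increment: the shock is re-applied per regime
        shared = pattern.copy()
        total_event = shared[e]
        # decompose: non-event pattern keeps sigma structure; event-year value
        # = pattern value minus the country shock, so that adding the weighted
        # regime shocks reconstructs the exact pattern
        shared[e] = total_event - k_country
    else:
        shared = rng.normal(0.0, 1.0, n_years)

    records: List[GridCellYield] = []
    for c in range(n_cells):
        cell_eps = (
            rng.normal(0.0, cell_noise_sd, n_years) if cell_noise_sd > 0 else 0.0
        )
        y_rf = (
            base_yield_rainfed
            + trend_slope * t
            + sigma_scale * (shared + cell_eps)
        )
        y_irr = (
            base_yield_irrigated
            + trend_slope * t
            + sigma_scale * (shared + cell_eps)
        )
        y_rf[e] += sigma_scale * shock_rainfed_sigma
        y_irr[e] += sigma_scale * shock_irrigated_sigma
        y_rf = np.clip(y_rf, 0.0, None)
        y_irr = np.clip(y_irr, 0.0, None)
        for j, yr in enumerate(years):
            records.append(
                GridCellYield(
                    cell=f"cell_{c:03d}",
                    year=int(yr),
                    yield_irrigated=float(y_irr[j]),
                    yield_rainfed=float(y_rf[j]),
                    frac_irrigated=float(f_irr[c]),
                    frac_rainfed=float(1.0 - f_irr[c]),
                    harvested_area=float(areas[c]),
                )
            )
    truth = GridYieldGroundTruth(
        country_shock_sigma=k_country,
        shock_rainfed_sigma=shock_rainfed_sigma,
        shock_irrigated_sigma=shock_irrigated_sigma,
    )
    return records, truth
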