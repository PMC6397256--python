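"""Sector-specific aggregation preceding the anomaly computation.

Agriculture: per-cell total yield is the cell-fraction-weighted combination
of irrigated and rainfed yields; country yield is the harvested-area-weighted
mean over cells.

Energy: hydropower usable capacity per plant is P = rho g Q H eta (capped at
the nameplate installed capacity), summed over a country's plants per time
step and averaged to annual values.  Countries with fewer than 20 plants or
under 100 MW total installed capacity are excluded from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .anomaly import AnnualSeries
from .errors import CountryExcludedError, InvalidInputError, NoCultivationError

RHO_WATER = 1000.0  # kg/m^3, freshwater density
G_ACCEL = 9.81  # m/s^2

MIN_PLANTS = 20
MIN_INSTALLED_MW = 100.0

_FRAC_TOL = 1e-9


@dataclass(frozen=True)
class GridCellYield:
    """One grid cell-year: irrigated/rainfed yields (t/ha) and area shares."""

    cell: str
    year: int
    yield_irrigated: float
    yield_rainfed: float
    frac_irrigated: float
    frac_rainfed: float
    harvested_area: float

    def __post_init__(self) -> None:
        if self.frac_irrigated < 0 or self.frac_rainfed < 0:
            raise InvalidInputError(f"cell {self.cell}: negative area fraction")
        if self.frac_irrigated + self.frac_rainfed > 1 + _FRAC_TOL:
            raise InvalidInputError(
                f"cell {self.cell}: area fractions sum to more than 1"
            )
        if self.yield_irrigated < 0 or self.yield_rainfed < 0:
            raise InvalidInputError(f"cell {self.cell}: negative yield")
        if self.harvested_area < 0:
            raise InvalidInputError(f"cell {self.cell}: negative harvested area")


@dataclass(frozen=True)
class HydroPlant:
    """A hydropower plant: discharge Q (m^3/s), head H (m), efficiency eta."""

    plant_id: str
    country: str
    discharge: float
    head: float
    efficiency: float
    installed_capacity_mw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.discharge < 0:
            raise InvalidInputError(f"plant {self.plant_id}: discharge must be >= 0")
        if self.head <= 0:
            raise InvalidInputError(f"plant {self.plant_id}: head must be > 0")
        if not 0 < self.efficiency <= 1:
            raise InvalidInputError(f"plant {self.plant_id}: efficiency must be in (0, 1]")
        if self.installed_capacity_mw is not None and self.installed_capacity_mw < 0:
            raise InvalidInputError(f"plant {self.plant_id}: negative installed capacity")


# ---------------------------------------------------------------------------
# Agriculture
# ---------------------------------------------------------------------------


def combine_yields(cell: GridCellYield) -> float:
    """Cell total yield (t/ha): fraction-weighted mean of irrigated and rainfed.

    y = (f_irr * y_irr + f_rf * y_rf) / (f_irr + f_rf); always lies between
    the two regime yields.
    """
    f_tot = cell.frac_irrigated + cell.frac_rainfed
    if f_tot <= 0:
        raise NoCultivationError(f"cell {cell.cell}: no cultivated area")
    return (
        cell.frac_irrigated * cell.yield_irrigated
        + cell.frac_rainfed * cell.yield_rainfed
    ) / f_tot


def aggregate_country_yield(
    cells: Sequence[GridCellYield], weighting: str = "harvested_area"
) -> float:
    """Country-year yield (t/ha) from its grid cells.

    ``weighting="harvested_area"`` (default) weights each cell's combined
    yield by its harvested area; ``"cultivated_area"`` weights by harvested
    area times the cultivated fraction.
    """
    if not cells:
        raise InvalidInputError("no cells to aggregate")
    years = {c.year for c in cells}
    if len(years) != 1:
        raise InvalidInputError(f"cells span multiple years {sorted(years)}")
    if weighting == "harvested_area":
        weights = np.array([c.harvested_area for c in cells], dtype=float)
    elif weighting == "cultivated_area":
        weights = np.array(
            [c.harvested_area * (c.frac_irrigated + c.frac_rainfed) for c in cells],
            dtype=float,
        )
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    if weights.sum() <= 0:
        raise InvalidInputError("total weight is zero")
    yields = np.array([combine_yields(c) for c in cells])
    return float(np.average(yields, weights=weights))


def country_yield_series(
    cells: Iterable[GridCellYield],
    units: str = "t/ha",
    weighting: str = "harvested_area",
) -> AnnualSeries:
    """Annual country yield series from a multi-year collection of cells."""
    by_year: dict[int, List[GridCellYield]] = {}
    for c in cells:
        by_year.setdefault(int(c.year), []).append(c)
    if not by_year:
        raise InvalidInputError("no cells provided")
    years = sorted(by_year)
    values = [aggregate_country_yield(by_year[y], weighting) for y in years]
    return AnnualSeries(np.array(years), np.array(values), units=units)


# ---------------------------------------------------------------------------
# Energy (hydropower)
# ---------------------------------------------------------------------------


def usable_capacity(plant: HydroPlant, discharge: Optional[float] = None) -> float:
    """Usable capacity in watts: P = rho g Q H eta, capped at nameplate.

    ``discharge`` overrides the plant's stored discharge (for time-varying
    streamflow).  Usable capacity is the maximum available output, which can
    exceed realised generation but never the installed capacity.
    """
    q = plant.discharge if discharge is None else float(discharge)
    if q < 0:
        raise InvalidInputError("discharge must be >= 0")
    p = RHO_WATER * G_ACCEL * q * plant.head * plant.efficiency
    if plant.installed_capacity_mw is not None:
        p = min(p, plant.installed_capacity_mw * 1e6)
    return p


def country_hydro_filter(plants: Sequence[HydroPlant]) -> bool:
    """Include a country iff it has >= 20 plants and >= 100 MW installed."""
    total_mw = sum(p.installed_capacity_mw or 0.0 for p in plants)
    return len(plants) >= MIN_PLANTS and total_mw >= MIN_INSTALLED_MW


def aggregate_country_capacity(
    plants: Sequence[HydroPlant],
    discharge: pd.DataFrame,
    units: str = "MW",
    apply_filter: bool = True,
) -> AnnualSeries:
    """Annual country usable capacity (MW) from per-plant discharge series.

    ``discharge`` is a long table with columns ``plant_id, date, discharge``
    (any sub-annual or annual time step).  Per time step, each plant's capped
    usable capacity is computed and summed across plants; annual values are
    the mean over that year's time steps.
    """
    if apply_filter and not country_hydro_filter(plants):
        total = sum(p.installed_capacity_mw or 0.0 for p in plants)
        raise CountryExcludedError(
            f"country excluded: {len(plants)} plants, {total:.1f} MW installed "
            f"(need >= {MIN_PLANTS} plants and >= {MIN_INSTALLED_MW} MW)"
        )
    for col in ("plant_id", "date", "discharge"):
        if col not in discharge.columns:
            raise InvalidInputError(f"discharge table missing column {col!r}")
    by_id = {p.plant_id: p for p in plants}
    unknown = set(discharge["plant_id"]) - set(by_id)
    if unknown:
        raise InvalidInputError(f"discharge rows for unknown plants {sorted(unknown)}")
    df = discharge.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["capacity_w"] = [
        usable_capacity(by_id[pid], q)
        for pid, q in zip(df["plant_id"], df["discharge"])
    ]
    per_step = df.groupby("date")["capacity_w"].sum()
    annual = per_step.groupby(per_step.index.year).mean() / 1e6
    return AnnualSeries(annual.index.to_numpy(), annual.to_numpy(), units=units)
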