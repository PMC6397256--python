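"""CSV/JSON readers and writers.

All delimited inputs are plain CSV with a header row; lines starting with
``#`` are comments.  Output files embed full parameter provenance as
``# key: value`` comment lines (CSV) or a ``"provenance"`` object (JSON), so
every result can be traced to the detrend method, sigma window, event year
and seed that produced it.

Canonical annual input is long format with an ``id`` column (one series per
station/country/model), or a bare ``year,value`` table for a single series.
Case tables for the ensemble evaluation are accepted wide
(``model_1..model_n`` columns) or long (a ``model,value`` pair per row).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .anomaly import AnnualSeries, AnomalyResult
from .ensemble import EvaluationCase
from .errors import InvalidInputError
from .mortality import ExposureResponse, MortalityEstimate, validate_weather_frame
from .sectors import GridCellYield, HydroPlant

PathLike = Union[str, Path]


def _read_csv(path: PathLike, **kw) -> pd.DataFrame:
    try:
        # exact IEEE round trip so written files re-read to identical doubles
        return pd.read_csv(path, comment="#", float_precision="round_trip", **kw)
    except (ValueError, OSError) as exc:
        raise InvalidInputError(f"cannot read {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    for c in cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise InvalidInputError(f"{path}: non-numeric values in column {c!r}") from exc


def provenance_lines(provenance: Optional[Mapping]) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


# ---------------------------------------------------------------------------
# Annual series
# ---------------------------------------------------------------------------


def read_annual_csv(
    path: PathLike,
    id_column: Optional[str] = None,
    units: str = "",
    allow_gaps: bool = False,
) -> Union[AnnualSeries, Dict[str, AnnualSeries]]:
    """Read ``year,value`` (single series) or ``id,year,value`` (long) CSV."""
    df = _read_csv(path)
    _require_columns(df, ["year", "value"], path)
    if id_column is None and "id" in df.columns:
        id_column = "id"
    _numeric(df, ["year", "value"], path)

    def one(group: pd.DataFrame, label: str) -> AnnualSeries:
        if group["year"].duplicated().any():
            dups = sorted(group.loc[group["year"].duplicated(), "year"].unique())
            raise InvalidInputError(f"{path}: duplicate years {dups} for {label!r}")
        group = group.sort_values("year")
        return AnnualSeries(
            group["year"].to_numpy(dtype=int),
            group["value"].to_numpy(dtype=float),
            units=units,
            allow_gaps=allow_gaps,
        )

    if id_column is None:
        return one(df, "series")
    _require_columns(df, [id_column], path)
    return {
        str(key): one(group, str(key)) for key, group in df.groupby(id_column)
    }


def write_annual_csv(
    series: Union[AnnualSeries, Mapping[str, AnnualSeries]],
    path: PathLike,
    provenance: Optional[Mapping] = None,
) -> None:
    """Write one series (``year,value``) or many (``id,year,value``)."""
    if isinstance(series, AnnualSeries):
        df = pd.DataFrame({"year": series.years, "value": series.values})
    else:
        frames = [
            pd.DataFrame({"id": name, "year": s.years, "value": s.values})
            for name, s in series.items()
        ]
        df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(provenance_lines(provenance))
        df.to_csv(fh, index=False)


def read_daily_csv(path: PathLike, units: str = "") -> pd.Series:
    """Read a ``date,value`` daily CSV into a datetime-indexed Series."""
    df = _read_csv(path)
    _require_columns(df, ["date", "value"], path)
    _numeric(df, ["value"], path)
    idx = pd.to_datetime(df["date"])
    if idx.duplicated().any():
        raise InvalidInputError(f"{path}: duplicate dates")
    out = pd.Series(df["value"].to_numpy(), index=pd.DatetimeIndex(idx))
    out.attrs["units"] = units
    return out.sort_index()


def write_anomalies_csv(
    results: Mapping[str, AnomalyResult],
    path: PathLike,
    provenance: Optional[Mapping] = None,
) -> None:
    rows = [{"id": name, **res.to_dict()} for name, res in results.items()]
    with open(path, "w") as fh:
        fh.write(provenance_lines(provenance))
        pd.DataFrame(rows).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Weather / ERF / mortality
# ---------------------------------------------------------------------------


def read_weather_csv(path: PathLike) -> pd.DataFrame:
    df = _read_csv(path)
    return validate_weather_frame(df)


def write_weather_csv(
    weather: pd.DataFrame, path: PathLike, provenance: Optional[Mapping] = None
) -> None:
    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write(provenance_lines(provenance))
        df.to_csv(fh, index=False)


ERF_COLUMNS = (
    "city",
    "threshold_at",
    "slope_lo",
    "slope_central",
    "slope_hi",
    "baseline_daily_deaths",
    "population",
)


def read_erf_csv(
    path: PathLike, slopes_as_percent: bool = False, convention: str = "log"
) -> List[ExposureResponse]:
    """Read a city ERF table; slopes are log-linear b unless flagged percent."""
    df = _read_csv(path)
    _require_columns(df, ERF_COLUMNS, path)
    _numeric(df, [c for c in ERF_COLUMNS if c != "city"], path)
    out = []
    for _, row in df.iterrows():
        if slopes_as_percent:
            out.append(
                ExposureResponse.from_percent_slopes(
                    city=str(row["city"]),
                    threshold_at=row["threshold_at"],
                    pct_central=row["slope_central"],
                    pct_lo=row["slope_lo"],
                    pct_hi=row["slope_hi"],
                    baseline_daily_deaths=row["baseline_daily_deaths"],
                    population=row["population"],
                    convention=convention,
                )
            )
        else:
            out.append(
                ExposureResponse(
                    city=str(row["city"]),
                    threshold_at=row["threshold_at"],
                    slope_central=row["slope_central"],
                    slope_lo=row["slope_lo"],
                    slope_hi=row["slope_hi"],
                    baseline_daily_deaths=row["baseline_daily_deaths"],
                    population=row["population"],
                )
            )
    return out


def write_mortality_json(
    estimates: Sequence[MortalityEstimate],
    path: PathLike,
    provenance: Optional[Mapping] = None,
) -> None:
    payload = {
        "provenance": dict(provenance or {}),
        "estimates": [e.to_dict() for e in estimates],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Yields / hydropower
# ---------------------------------------------------------------------------

YIELD_COLUMNS = ("cell", "year", "yield_irr", "yield_rf", "frac_irr", "frac_rf", "area")


def read_yields_csv(path: PathLike) -> List[GridCellYield]:
    df = _read_csv(path)
    _require_columns(df, YIELD_COLUMNS, path)
    _numeric(df, [c for c in YIELD_COLUMNS if c != "cell"], path)
    return [
        GridCellYield(
            cell=str(r["cell"]),
            year=int(r["year"]),
            yield_irrigated=float(r["yield_irr"]),
            yield_rainfed=float(r["yield_rf"]),
            frac_irrigated=float(r["frac_irr"]),
            frac_rainfed=float(r["frac_rf"]),
            harvested_area=float(r["area"]),
        )
        for _, r in df.iterrows()
    ]


def write_yields_csv(
    cells: Sequence[GridCellYield], path: PathLike, provenance: Optional[Mapping] = None
) -> None:
    df = pd.DataFrame(
        {
            "cell": [c.cell for c in cells],
            "year": [c.year for c in cells],
            "yield_irr": [c.yield_irrigated for c in cells],
            "yield_rf": [c.yield_rainfed for c in cells],
            "frac_irr": [c.frac_irrigated for c in cells],
            "frac_rf": [c.frac_rainfed for c in cells],
            "area": [c.harvested_area for c in cells],
        }
    )
    with open(path, "w") as fh:
        fh.write(provenance_lines(provenance))
        df.to_csv(fh, index=False)


PLANT_COLUMNS = ("id", "country", "Q", "H", "eta", "installed_mw")


def read_plants_csv(path: PathLike) -> Dict[str, List[HydroPlant]]:
    """Plants grouped by country."""
    df = _read_csv(path)
    _require_columns(df, PLANT_COLUMNS, path)
    _numeric(df, ["Q", "H", "eta", "installed_mw"], path)
    out: Dict[str, List[HydroPlant]] = {}
    for _, r in df.iterrows():
        plant = HydroPlant(
            plant_id=str(r["id"]),
            country=str(r["country"]),
            discharge=float(r["Q"]),
            head=float(r["H"]),
            efficiency=float(r["eta"]),
            installed_capacity_mw=float(r["installed_mw"]),
        )
        out.setdefault(plant.country, []).append(plant)
    return out


def read_discharge_csv(path: PathLike) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["plant_id", "date", "discharge"], path)
    _numeric(df, ["discharge"], path)
    df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# Evaluation cases
# ---------------------------------------------------------------------------


def read_cases_csv(path: PathLike) -> List[EvaluationCase]:
    """Read cases, wide (``model_1..model_n``) or long (``model,value``)."""
    df = _read_csv(path)
    base = ["case_id", "sector", "observed", "threshold", "sign"]
    _require_columns(df, base, path)
    model_cols = [c for c in df.columns if c.startswith("model_") or c == "model"]
    if not model_cols:
        raise InvalidInputError(f"{path}: no model columns found")
    cases: List[EvaluationCase] = []
    if "model" in df.columns:  # long format
        _require_columns(df, ["value"], path)
        _numeric(df, ["observed", "threshold", "sign", "value"], path)
        for cid, group in df.groupby("case_id", sort=False):
            head = group.iloc[0]
            cases.append(
                EvaluationCase(
                    case_id=str(cid),
                    sector=str(head["sector"]),
                    observed=float(head["observed"]),
                    simulated=tuple(group["value"].astype(float)),
                    severity_threshold=float(head["threshold"]),
                    sign_of_harm=int(head["sign"]),
                )
            )
    else:  # wide format
        wide = [c for c in df.columns if c.startswith("model_")]
        _numeric(df, ["observed", "threshold", "sign"], path)
        for _, r in df.iterrows():
            sims = [float(r[c]) for c in wide if pd.notna(r[c])]
            cases.append(
                EvaluationCase(
                    case_id=str(r["case_id"]),
                    sector=str(r["sector"]),
                    observed=float(r["observed"]),
                    simulated=tuple(sims),
                    severity_threshold=float(r["threshold"]),
                    sign_of_harm=int(r["sign"]),
                )
            )
    return cases


def write_cases_csv(
    cases: Sequence[EvaluationCase], path: PathLike, provenance: Optional[Mapping] = None
) -> None:
    n_max = max(len(c.simulated) for c in cases)
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "sector": c.sector,
            "observed": c.observed,
            "threshold": c.severity_threshold,
            "sign": c.sign_of_harm,
        }
        for i in range(n_max):
            row[f"model_{i + 1}"] = c.simulated[i] if i < len(c.simulated) else ""
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(provenance_lines(provenance))
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_summary_json(
    summary,
    classifications: Mapping[str, str],
    path: PathLike,
    provenance: Optional[Mapping] = None,
) -> None:
    payload = {
        "provenance": dict(provenance or {}),
        "summary": summary.to_dict(),
        "classifications": dict(classifications),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Flat key=value run configuration (CLI defaults)."""

    sector: str = ""
    detrend: str = "linear"
    window: int = 7
    event_year: int = 2003
    sigma_start: Optional[int] = None
    sigma_end: Optional[int] = None
    month: Optional[int] = None
    severity_threshold: float = 1.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: PathLike) -> "RunConfig":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InvalidInputError(f"{path}:{lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if not hasattr(cfg, key):
                raise InvalidInputError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int) or (current is None and key != "sector"):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg
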