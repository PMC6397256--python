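"""A scripted multi-sector evaluation scenario with known ground truth.

Emulates the structure of a multi-sector extreme-event model evaluation:
river-discharge-like cases (linear detrend, 7 hydrological models),
crop-yield-like cases (7-year moving-average detrend, 8 crop models), and
city mortality cases (3 climate forcings through the exposure-response
model).  Every case carries a designed classification; in the noiseless
limit the full pipeline (generate -> anomaly / mortality -> classify) must
recover the design exactly, and under noise at a rate consistent with the
misclassification probability implied by the generative model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .anomaly import DetrendSpec, standardized_anomaly
from .ensemble import (
    CAPTURED,
    FALSE_ALARM,
    MORTALITY_SEVERITY_PER_100K,
    SIGMA_SEVERITY,
    UNDERESTIMATED_BY_75PLUS,
    UNDERESTIMATED_BY_ALL,
    UNREMARKABLE,
    CrossSectorSummary,
    EvaluationCase,
)
from .mortality import ExposureResponse, estimate_mortality
from .synthetic import EnsembleScenario, WeatherScenario, gen_annual_ensemble, gen_daily_weather

LINEAR = DetrendSpec("linear")
MA7 = DetrendSpec("moving_average", 7)

#: (label, event sigma magnitude, per-model attenuations, designed category)
RIVER_DESIGN: List[Tuple[str, float, Tuple[float, ...], str]] = (
    [(f"river_{i:02d}", -2.0, (1.25,) * 7, CAPTURED) for i in range(1, 6)]
    + [(f"river_{i:02d}", -0.5, (6.0,) * 7, FALSE_ALARM) for i in range(6, 10)]
    + [(f"river_{i:02d}", -0.3, (1.0,) * 7, UNREMARKABLE) for i in range(10, 13)]
)

CROP_DESIGN: List[Tuple[str, float, Tuple[float, ...], str]] = (
    [(f"crop_{i:02d}", -3.0, (0.3,) * 8, UNDERESTIMATED_BY_ALL) for i in range(1, 4)]
    + [
        (f"crop_{i:02d}", -3.0, (0.3,) * 7 + (1.3,), UNDERESTIMATED_BY_75PLUS)
        for i in range(4, 7)
    ]
    + [(f"crop_{i:02d}", -2.0, (1.3,) * 8, CAPTURED) for i in range(7, 9)]
    + [(f"crop_{i:02d}", -0.2, (1.0,) * 8, UNREMARKABLE) for i in range(9, 11)]
)

#: (city, heat-wave amplitude deg C, per-forcing attenuations, designed category)
CITY_DESIGN: List[Tuple[str, float, Tuple[float, ...], str]] = [
    ("city_alpha", 10.0, (0.5, 0.5, 0.5), UNDERESTIMATED_BY_ALL),
    ("city_beta", 9.0, (0.4, 0.5, 0.6), UNDERESTIMATED_BY_ALL),
    ("city_gamma", 10.0, (1.3, 1.3, 1.3), CAPTURED),
]

#: One warm-season ERF reused for all synthetic cities.
CITY_ERF_PARAMS = dict(
    threshold_at=30.0,
    slope_central=0.05,
    slope_lo=0.03,
    slope_hi=0.08,
    baseline_daily_deaths=30.0,
    population=1_000_000.0,
)

SUMMER = ("2003-06-01", "2003-08-31")


@dataclass(frozen=True)
class MultisectorScenario:
    """Generated cases plus the classification they were designed to have."""

    cases: List[EvaluationCase]
    designed_categories: Dict[str, str]
    designed_summary: CrossSectorSummary


def _sigma_case(
    case_id: str,
    sector: str,
    k: float,
    attenuation: Tuple[float, ...],
    detrend: DetrendSpec,
    noise_sd: float,
    seed: int,
) -> EvaluationCase:
    scn = EnsembleScenario(
        n_years=30,
        start_year=1979,
        event_year=2003,
        intercept=100.0,
        trend_slope=0.5 if detrend.method != "constant" else 0.0,
        noise_sd=noise_sd,
        event_magnitude_sigma=k,
        n_models=len(attenuation),
        attenuation=attenuation,
        detrend=detrend,
        seed=seed,
    )
    observed, models, _ = gen_annual_ensemble(scn)
    obs_anom = standardized_anomaly(observed, 2003, detrend).anomaly_sigma
    sim_anoms = [standardized_anomaly(m, 2003, detrend).anomaly_sigma for m in models]
    return EvaluationCase(
        case_id=case_id,
        sector=sector,
        observed=obs_anom,
        simulated=tuple(sim_anoms),
        severity_threshold=SIGMA_SEVERITY,
        sign_of_harm=-1,
    )


def _city_case(
    city: str,
    amplitude: float,
    attenuation: Tuple[float, ...],
    noise_sd: float,
    seed: int,
) -> EvaluationCase:
    erf = ExposureResponse(city=city, **CITY_ERF_PARAMS)
    rh_sd = 8.0 if noise_sd > 0 else 0.0

    def rate(amp: float, sub_seed: int) -> float:
        weather = gen_daily_weather(
            WeatherScenario(
                heatwave_start="2003-07-20",
                heatwave_end="2003-08-14",
                heatwave_amplitude=amp,
                noise_sd=noise_sd,
                rh_sd=rh_sd,
                seed=sub_seed,
            )
        )
        return estimate_mortality(erf, weather, SUMMER).rate_central

    observed = rate(amplitude, seed)
    simulated = tuple(
        rate(a * amplitude, seed + 1 + m) for m, a in enumerate(attenuation)
    )
    return EvaluationCase(
        case_id=city,
        sector="mortality",
        observed=observed,
        simulated=simulated,
        severity_threshold=MORTALITY_SEVERITY_PER_100K,
        sign_of_harm=+1,
    )


def build_multisector_scenario(
    seed: int = 0, noise_sd: float = 0.0
) -> MultisectorScenario:
    """12 river-like + 10 crop-like + 3 mortality cases with designed classes.

    ``noise_sd = 0`` uses the exact generators (designed classification is
    recovered with certainty); ``noise_sd > 0`` sets the interannual /
    day-to-day noise standard deviation (sigma units are unchanged because
    the event shock scales with the noise).
    """
    cases: List[EvaluationCase] = []
    designed: Dict[str, str] = {}
    sub = int(seed) * 1009 % (2**31 - 2000)
    for i, (cid, k, att, cat) in enumerate(RIVER_DESIGN):
        cases.append(_sigma_case(cid, "river_discharge", k, att, LINEAR, noise_sd, sub + i))
        designed[cid] = cat
    for i, (cid, k, att, cat) in enumerate(CROP_DESIGN):
        cases.append(
            _sigma_case(cid, "crop_yield", k, att, MA7, noise_sd, sub + 100 + i)
        )
        designed[cid] = cat
    for i, (city, amp, att, cat) in enumerate(CITY_DESIGN):
        cases.append(_city_case(city, amp, att, noise_sd, sub + 200 + 10 * i))
        designed[city] = cat

    counts = {c: 0 for c in (UNDERESTIMATED_BY_ALL, UNDERESTIMATED_BY_75PLUS,
                             CAPTURED, FALSE_ALARM, UNREMARKABLE)}
    for cat in designed.values():
        counts[cat] += 1
    n_severe = (
        counts[UNDERESTIMATED_BY_ALL]
        + counts[UNDERESTIMATED_BY_75PLUS]
        + counts[CAPTURED]
    )
    summary = CrossSectorSummary(
        n_cases=len(cases),
        n_severe_observed=n_severe,
        n_underestimated_75plus=counts[UNDERESTIMATED_BY_ALL]
        + counts[UNDERESTIMATED_BY_75PLUS],
        n_underestimated_all=counts[UNDERESTIMATED_BY_ALL],
        n_false_alarms=counts[FALSE_ALARM],
    )
    return MultisectorScenario(cases=cases, designed_categories=designed,
                               designed_summary=summary)
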