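"""Multi-model ensemble summaries and under/over-estimation classification.

A case pairs one observed anomaly with the simulated anomalies of a model
ensemble, in common units (standard deviations, or excess deaths per 100,000
for mortality).  A case is *severe* when the observed anomaly exceeds the
severity threshold on the harmful side (default 1 sigma; 10 per 100,000 for
mortality).  For severe cases, a model *underestimates* when its anomaly is
strictly less harmful than observed; the case is classified by how much of
the ensemble underestimates.  For non-severe cases, a *false alarm* is
declared when at least 75% of the models simulate an anomaly beyond the
severity threshold.

Harm direction: deficit indicators (discharge, yield, productivity, capacity)
use ``sign_of_harm=-1`` (more negative is more harmful); mortality uses
``+1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

UNDERESTIMATED_BY_ALL = "underestimated_by_all"
UNDERESTIMATED_BY_75PLUS = "underestimated_by_75plus"
CAPTURED = "captured"
FALSE_ALARM = "false_alarm"
UNREMARKABLE = "unremarkable"

CATEGORIES = (
    UNDERESTIMATED_BY_ALL,
    UNDERESTIMATED_BY_75PLUS,
    CAPTURED,
    FALSE_ALARM,
    UNREMARKABLE,
)

SEVERE_CATEGORIES = (UNDERESTIMATED_BY_ALL, UNDERESTIMATED_BY_75PLUS, CAPTURED)

#: Default severity thresholds by unit system.
SIGMA_SEVERITY = 1.0
MORTALITY_SEVERITY_PER_100K = 10.0


@dataclass(frozen=True)
class EvaluationCase:
    """One observed anomaly versus an ensemble of simulated anomalies."""

    case_id: str
    sector: str
    observed: float
    simulated: tuple
    severity_threshold: float = SIGMA_SEVERITY
    sign_of_harm: int = -1

    def __post_init__(self) -> None:
        sims = tuple(float(v) for v in self.simulated)
        if len(sims) == 0:
            raise InvalidInputError(f"case {self.case_id}: empty model ensemble")
        if self.sign_of_harm not in (-1, 1):
            raise InvalidInputError(f"case {self.case_id}: sign_of_harm must be -1 or +1")
        if self.severity_threshold <= 0:
            raise InvalidInputError(f"case {self.case_id}: threshold must be > 0")
        object.__setattr__(self, "simulated", sims)


@dataclass(frozen=True)
class EnsembleSummary:
    """Median, quartiles and range of the simulated anomalies."""

    median: float
    q25: float
    q75: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {"median": self.median, "q25": self.q25, "q75": self.q75,
                "min": self.min, "max": self.max}


@dataclass(frozen=True)
class CrossSectorSummary:
    """Tallies of the classification across all cases.

    ``n_underestimated_75plus`` counts severe cases where at least 75% of the
    models (including the all-models cases) underestimate;
    ``n_underestimated_all`` counts only the cases missed by every model, so
    ``n_all <= n_75plus <= n_severe <= n_cases``.
    """

    n_cases: int
    n_severe_observed: int
    n_underestimated_75plus: int
    n_underestimated_all: int
    n_false_alarms: int

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_severe_observed": self.n_severe_observed,
            "n_underestimated_75plus": self.n_underestimated_75plus,
            "n_underestimated_all": self.n_underestimated_all,
            "n_false_alarms": self.n_false_alarms,
        }


def ensemble_stats(simulated: Sequence[float]) -> EnsembleSummary:
    """Median, interquartile range and full range of an ensemble.

    Quartiles use linear interpolation between order statistics (position
    (n-1)p), numpy's default.
    """
    sims = np.asarray(list(simulated), dtype=float)
    if sims.size == 0:
        raise InvalidInputError("empty model ensemble")
    q25, med, q75 = np.quantile(sims, [0.25, 0.5, 0.75], method="linear")
    return EnsembleSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        min=float(sims.min()), max=float(sims.max()),
    )


def classify_case(case: EvaluationCase) -> str:
    """Classify one case into exactly one of the five categories.

    In harm units (observed and simulated multiplied by ``sign_of_harm`` so
    that larger means more harmful):

    * severe observed (harm > threshold, strictly):
      every model strictly less harmful       -> underestimated_by_all;
      at least 75% (but not all) strictly less -> underestimated_by_75plus;
      otherwise                                -> captured
      (a model exactly equal to the observation does not underestimate);
    * non-severe observed:
      at least 75% of models strictly beyond the threshold -> false_alarm;
      otherwise                                            -> unremarkable.

    The 75% rule is inclusive and computed without rounding
    (4 * count >= 3 * n).
    """
    harm_obs = case.sign_of_harm * case.observed
    harm_sim = [case.sign_of_harm * v for v in case.simulated]
    n = len(harm_sim)
    if harm_obs > case.severity_threshold:
        n_under = sum(1 for h in harm_sim if h < harm_obs)
        if n_under == n:
            return UNDERESTIMATED_BY_ALL
        if 4 * n_under >= 3 * n:
            return UNDERESTIMATED_BY_75PLUS
        return CAPTURED
    n_beyond = sum(1 for h in harm_sim if h > case.severity_threshold)
    if 4 * n_beyond >= 3 * n:
        return FALSE_ALARM
    return UNREMARKABLE


def count_summary(cases: Sequence[EvaluationCase]) -> CrossSectorSummary:
    """Cross-sector tallies of the case classification."""
    if not cases:
        raise InvalidInputError("no cases to summarise")
    cats = [classify_case(c) for c in cases]
    n_all = cats.count(UNDERESTIMATED_BY_ALL)
    n_75 = n_all + cats.count(UNDERESTIMATED_BY_75PLUS)
    n_severe = sum(cats.count(c) for c in SEVERE_CATEGORIES)
    return CrossSectorSummary(
        n_cases=len(cases),
        n_severe_observed=n_severe,
        n_underestimated_75plus=n_75,
        n_underestimated_all=n_all,
        n_false_alarms=cats.count(FALSE_ALARM),
    )
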