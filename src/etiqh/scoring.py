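"""Two-step weighted score calculation.

For one facility visit, the quality level of dimension *d* is computed in two
steps over that sub-tool's verification criteria:

1. **Criterion averaging.** For criterion *c*, the proportion met is

       p_c = (# yes) / (# yes + # no)

   over all respondents or observations; explicit NA answers drop out of both
   numerator and denominator. A criterion with no yes/no answer at all (all
   NA, or belonging to an unobserved scenario) is *undefined*.

2. **Weighting.** With importance weights w_c (normally 1–5),

       S_d = 100 · Σ_c w_c · p_c / Σ_c w_c

   summing over the *defined* criteria only, so the achievable points
   contract when criteria do not apply — exactly the behaviour implied by
   maximum points "per respondent interviewed" and "if all four clinical
   scenarios are observed".

The overall facility score is the unweighted arithmetic mean of the defined
dimension percentages. Scores below the satisfactory threshold (75 % by
convention, strict) are classed "unsatisfactory".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .assessments import AssessmentSession, ResponseValue
from .instrument import Instrument, Scenario

__all__ = [
    "CriterionScore",
    "SubToolScore",
    "FacilityScore",
    "ScenarioScore",
    "NoDefinedCriteriaError",
    "ScenarioNotObservedError",
    "criterion_proportion",
    "subtool_score",
    "facility_score",
    "score_sessions",
    "scenario_score",
    "classify",
    "scores_frame",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 75.0

SATISFACTORY = "satisfactory"
UNSATISFACTORY = "unsatisfactory"


class NoDefinedCriteriaError(ValueError):
    """Every criterion of a sub-tool is undefined — the sub-tool is un-scorable."""

    def __init__(self, subtool_index: int):
        self.subtool_index = subtool_index
        super().__init__(f"sub-tool {subtool_index}: no defined criteria (all NA or unanswered)")


class ScenarioNotObservedError(ValueError):
    def __init__(self, scenario: Scenario):
        self.scenario = scenario
        super().__init__(f"scenario {scenario.value!r} was not observed in this session")


@dataclass(frozen=True)
class CriterionScore:
    """Proportion met for one criterion; undefined when no yes/no answer exists."""

    criterion_id: str
    n_responses: int
    proportion_met: float  # nan when undefined
    defined: bool


@dataclass(frozen=True)
class SubToolScore:
    """Weighted percentage for one quality dimension at one facility-round."""

    subtool_index: int
    points_achieved: float  # Σ w_c · p_c over defined criteria
    points_achievable: float  # Σ w_c over defined criteria
    percent: float
    n_criteria_defined: int


@dataclass(frozen=True)
class ScenarioScore:
    """Disease-specific score over one scenario's criteria (sub-tool 3)."""

    scenario: Scenario
    points_achieved: float
    points_achievable: float
    percent: float
    n_criteria_defined: int


@dataclass
class FacilityScore:
    """Per-dimension scores plus their unweighted mean (overall quality)."""

    facility_id: str
    round: str
    dimensions: dict[int, Optional[SubToolScore]] = field(default_factory=dict)
    overall_percent: float = math.nan
    n_dimensions_defined: int = 0

    def percent(self, subtool_index: int) -> float:
        sc = self.dimensions.get(subtool_index)
        return sc.percent if sc is not None else math.nan


def criterion_proportion(
    values: Iterable[ResponseValue | int], criterion_id: str = ""
) -> CriterionScore:
    """Average one criterion over respondents: p_c = yes / (yes + no).

    NA answers are excluded from numerator and denominator; with no yes/no
    answers the score is undefined (``defined=False``, proportion NaN).
    """
    yes = no = 0
    for v in values:
        code = int(v)
        if code == ResponseValue.YES:
            yes += 1
        elif code == ResponseValue.NO:
            no += 1
        elif code != ResponseValue.NA:
            raise ValueError(f"illegal response value {code}")
    n = yes + no
    if n == 0:
        return CriterionScore(criterion_id, 0, math.nan, False)
    return CriterionScore(criterion_id, n, yes / n, True)


def _weighted_percent(
    weights: Sequence[float], proportions: Sequence[float]
) -> tuple[float, float, float]:
    achieved = float(np.dot(weights, proportions))
    achievable = float(np.sum(weights))
    return achieved, achievable, 100.0 * achieved / achievable


def _criterion_stats(
    session: AssessmentSession, criterion_ids: set[str]
) -> dict[str, tuple[int, int]]:
    """(yes-count, non-NA count) per criterion; plain counting keeps scoring
    cheap for the many small sessions a council round produces."""
    counts: dict[str, tuple[int, int]] = {}
    for rec in session.records:
        cid = rec.criterion_id
        if cid not in criterion_ids:
            continue
        v = int(rec.value)
        if v == int(ResponseValue.NA):
            continue
        yes, n = counts.get(cid, (0, 0))
        counts[cid] = (yes + (v == int(ResponseValue.YES)), n + 1)
    return counts


def subtool_score(
    inst: Instrument, session: AssessmentSession, subtool_index: int
) -> SubToolScore:
    """Weighted percentage for one sub-tool of one session.

    Criteria tagged with a scenario not in ``session.scenario_observed`` are
    treated as NA regardless of any stray answers, so both achieved and
    achievable points contract. Raises :class:`NoDefinedCriteriaError` when no
    criterion has a yes/no answer.
    """
    st = inst.subtool(subtool_index)
    applicable = [
        c for c in st.criteria if c.scenario is None or c.scenario in session.scenario_observed
    ]
    stats = _criterion_stats(session, {c.id for c in applicable})
    weights, props = [], []
    for c in applicable:
        if c.id in stats:
            yes, n = stats[c.id]
            weights.append(c.weight)
            props.append(yes / n)
    if not weights:
        raise NoDefinedCriteriaError(subtool_index)
    achieved, achievable, percent = _weighted_percent(weights, props)
    return SubToolScore(subtool_index, achieved, achievable, percent, len(weights))


def scenario_score(
    inst: Instrument, session: AssessmentSession, scenario: Scenario | str
) -> ScenarioScore:
    """Disease-specific score restricted to one scenario's tagged criteria."""
    scenario = Scenario(scenario)
    if scenario not in session.scenario_observed:
        raise ScenarioNotObservedError(scenario)
    tagged = [c for _, c in inst.iter_criteria() if c.scenario == scenario]
    stats = _criterion_stats(session, {c.id for c in tagged})
    weights, props = [], []
    for c in tagged:
        if c.id in stats:
            yes, n = stats[c.id]
            weights.append(c.weight)
            props.append(yes / n)
    if not weights:
        raise NoDefinedCriteriaError(3)
    achieved, achievable, percent = _weighted_percent(weights, props)
    return ScenarioScore(scenario, achieved, achievable, percent, len(weights))


def facility_score(inst: Instrument, session: AssessmentSession) -> FacilityScore:
    """Score all six dimensions and their unweighted mean.

    A sub-tool with no defined criteria becomes an undefined dimension
    (``None``); the overall score averages the defined dimensions only and
    records how many there were.
    """
    dims: dict[int, Optional[SubToolScore]] = {}
    for st in sorted(inst.subtools, key=lambda s: s.index):
        try:
            dims[st.index] = subtool_score(inst, session, st.index)
        except NoDefinedCriteriaError:
            dims[st.index] = None
    defined = [sc.percent for sc in dims.values() if sc is not None]
    overall = float(np.mean(defined)) if defined else math.nan
    return FacilityScore(
        facility_id=session.facility_id,
        round=session.round,
        dimensions=dims,
        overall_percent=overall,
        n_dimensions_defined=len(defined),
    )


def score_sessions(inst: Instrument, sessions: Sequence[AssessmentSession]) -> list[FacilityScore]:
    """Convenience: score a batch of sessions."""
    return [facility_score(inst, s) for s in sessions]


def classify(percent: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'unsatisfactory' strictly below the threshold, else 'satisfactory'."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    return UNSATISFACTORY if percent < threshold else SATISFACTORY


def scores_frame(scores: Sequence[FacilityScore], decimals: Optional[int] = None) -> pd.DataFrame:
    """Tidy output table: one row per facility × round × dimension, plus an
    ``overall`` row per facility-round. Full precision unless ``decimals``
    is given (reports conventionally print one decimal)."""
    rows = []
    for fs in scores:
        for idx in sorted(fs.dimensions):
            sc = fs.dimensions[idx]
            rows.append(
                {
                    "facility_id": fs.facility_id,
                    "round": fs.round,
                    "dimension": str(idx),
                    "percent": sc.percent if sc is not None else math.nan,
                    "points_achieved": sc.points_achieved if sc is not None else math.nan,
                    "points_achievable": sc.points_achievable if sc is not None else math.nan,
                }
            )
        rows.append(
            {
                "facility_id": fs.facility_id,
                "round": fs.round,
                "dimension": "overall",
                "percent": fs.overall_percent,
                "points_achieved": math.nan,
                "points_achievable": math.nan,
            }
        )
    out = pd.DataFrame(rows)
    if decimals is not None and not out.empty:
        for col in ("percent", "points_achieved", "points_achievable"):
            out[col] = out[col].round(decimals)
    return out
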