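"""Shared fixtures: instruments, a small register, session builders, and an
independent brute-force scoring oracle used to cross-check the engine."""

from __future__ import annotations

import pandas as pd
import pytest

from etiqh.assessments import AssessmentSession, ResponseRecord, ResponseValue
from etiqh.instrument import FacilityType, Scenario, demo_instrument, reference_instrument

ALL_SCENARIOS = frozenset(Scenario)


@pytest.fixture(scope="session")
def demo_inst():
    return demo_instrument()


@pytest.fixture(scope="session")
def ref_inst():
    return reference_instrument()


@pytest.fixture()
def register4() -> pd.DataFrame:
    """Four facilities across two councils, mixed types and ownership."""
    reg = pd.DataFrame(
        [
            {"id": "F1", "name": "Disp 1", "type": "dispensary", "ownership": "public",
             "council": "C-East", "region": "R1"},
            {"id": "F2", "name": "Disp 2", "type": "dispensary", "ownership": "faith_based",
             "council": "C-East", "region": "R1"},
            {"id": "F3", "name": "HC 3", "type": "health_center", "ownership": "public",
             "council": "C-West", "region": "R1"},
            {"id": "F4", "name": "Hosp 4", "type": "hospital_opd", "ownership": "faith_based",
             "council": "C-West", "region": "R1"},
        ]
    )
    return reg.set_index("id", drop=False)


def build_session(
    inst,
    answers: dict[str, list[int]],
    facility_id: str = "F1",
    round: str = "2011",
    scenario_observed=ALL_SCENARIOS,
    facility_type: FacilityType = FacilityType.DISPENSARY,
) -> AssessmentSession:
    """Build a session from criterion_id -> per-respondent answer codes.

    Answer lists index respondents 1..n; a code of None skips that row
    (a genuinely missing answer, distinct from an explicit NA=99).
    """
    subtool_of = inst.criterion_subtool()
    records = []
    for cid, values in answers.items():
        for resp, code in enumerate(values, start=1):
            if code is None:
                continue
            records.append(
                ResponseRecord(
                    facility_id=facility_id,
                    round=round,
                    subtool_index=subtool_of[cid],
                    criterion_id=cid,
                    respondent=resp,
                    value=ResponseValue(code),
                )
            )
    return AssessmentSession(
        facility_id=facility_id,
        round=round,
        records=records,
        scenario_observed=frozenset(scenario_observed),
        facility_type=facility_type,
    )


def brute_force_percent(weighted_answers: dict[str, tuple[int, list[int]]]) -> float:
    """Independent oracle: enumerate answers directly.

    ``weighted_answers`` maps criterion id -> (weight, answer codes). Walks
    every answer one by one — no pandas, no shared code with the engine.
    """
    numerator = 0.0
    denominator = 0.0
    for _cid, (weight, codes) in weighted_answers.items():
        yes = no = 0
        for code in codes:
            if code == 1:
                yes += 1
            elif code == 0:
                no += 1
        if yes + no == 0:
            continue  # all NA: drops from both sums
        numerator += weight * yes / (yes + no)
        denominator += weight
    if denominator == 0:
        raise ZeroDivisionError("no defined criteria")
    return 100.0 * numerator / denominator


@pytest.fixture()
def make_session():
    return build_session


@pytest.fixture()
def oracle():
    return brute_force_percent
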