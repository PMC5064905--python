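"""Assessment sessions: raw yes/no/NA responses, registers, and validation.

A *session* is one assessment visit to one facility in one round. Responses
travel in a long ("tidy") CSV, one row per answer, with columns::

    facility_id, round, subtool, criterion_id, respondent, value

where ``value`` uses the wire codes 1 = yes, 0 = no, 99 = not applicable.
An explicit NA (99) means the criterion does not apply at this facility and
is clean data; a *missing row* is a different thing — it is flagged by
:func:`validate_session` as ``MISSING_ANSWER``, mirroring the bounce-back
behaviour of the original hand-held front end. Scoring treats both as
excluded, but only the explicit NA passes validation.

The facility register is a CSV with columns
``id, name, type, ownership, council, region``; rounds are opaque ordered
labels (typically calendar years).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .instrument import FacilityType, Instrument, Scenario

__all__ = [
    "Ownership",
    "Facility",
    "ResponseValue",
    "ResponseRecord",
    "AssessmentSession",
    "Issue",
    "IssueCode",
    "DataError",
    "load_register",
    "save_register",
    "read_responses",
    "write_responses",
    "sessions_from_frame",
    "validate_session",
]

RESPONSE_COLUMNS = ["facility_id", "round", "subtool", "criterion_id", "respondent", "value"]
REGISTER_COLUMNS = ["id", "name", "type", "ownership", "council", "region"]
SESSION_COLUMNS = ["facility_id", "round", "scenarios_observed"]


class DataError(ValueError):
    """Raised for malformed registers or response files (names the offender)."""


class Ownership(str, enum.Enum):
    PUBLIC = "public"
    FAITH_BASED = "faith_based"
    PRIVATE = "private"
    INSTITUTIONAL = "institutional"


@dataclass(frozen=True)
class Facility:
    id: str
    name: str
    type: FacilityType
    ownership: Ownership
    council: str
    region: str


class ResponseValue(enum.IntEnum):
    """Answer codes as stored on the wire: yes=1, no=0, not-applicable=99."""

    NO = 0
    YES = 1
    NA = 99


@dataclass(frozen=True)
class ResponseRecord:
    """One answer to one criterion by one respondent/observation."""

    facility_id: str
    round: str
    subtool_index: int
    criterion_id: str
    respondent: int
    value: ResponseValue


@dataclass
class AssessmentSession:
    """All responses from one facility visit in one round."""

    facility_id: str
    round: str
    records: list[ResponseRecord]
    scenario_observed: frozenset[Scenario] = frozenset()
    facility_type: Optional[FacilityType] = None
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view of the records (cached)."""
        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "facility_id": [r.facility_id for r in self.records],
                    "round": [r.round for r in self.records],
                    "subtool": [r.subtool_index for r in self.records],
                    "criterion_id": [r.criterion_id for r in self.records],
                    "respondent": [r.respondent for r in self.records],
                    "value": [int(r.value) for r in self.records],
                },
            )
        return self._frame


class IssueCode(str, enum.Enum):
    MISSING_ANSWER = "MISSING_ANSWER"
    RESPONDENT_COUNT = "RESPONDENT_COUNT"
    SCENARIO_GAP = "SCENARIO_GAP"
    EMPTY_INPUT = "EMPTY_INPUT"


@dataclass(frozen=True)
class Issue:
    """One validation finding; issues are data, not exceptions."""

    code: IssueCode
    facility_id: str
    round: str
    subtool_index: Optional[int] = None
    criterion_id: Optional[str] = None
    respondent: Optional[int] = None
    message: str = ""


# ---------------------------------------------------------------------------
# register I/O

def load_register(path: str | Path) -> pd.DataFrame:
    """Read and validate a facility register CSV, indexed by facility id."""
    reg = pd.read_csv(path, dtype=str)
    missing = [c for c in REGISTER_COLUMNS if c not in reg.columns]
    if missing:
        raise DataError(f"register {path}: missing columns {missing}")
    dup = reg["id"][reg["id"].duplicated()]
    if not dup.empty:
        raise DataError(f"register {path}: duplicate facility id {dup.iloc[0]!r}")
    bad_type = set(reg["type"]) - {t.value for t in FacilityType}
    if bad_type:
        raise DataError(f"register {path}: unknown facility type(s) {sorted(bad_type)}")
    bad_own = set(reg["ownership"]) - {o.value for o in Ownership}
    if bad_own:
        raise DataError(f"register {path}: unknown ownership value(s) {sorted(bad_own)}")
    return reg.set_index("id", drop=False)


def save_register(register: pd.DataFrame, path: str | Path) -> None:
    register[REGISTER_COLUMNS].to_csv(path, index=False)


def facility_from_register(register: pd.DataFrame, facility_id: str) -> Facility:
    row = register.loc[facility_id]
    return Facility(
        id=row["id"],
        name=row["name"],
        type=FacilityType(row["type"]),
        ownership=Ownership(row["ownership"]),
        council=row["council"],
        region=row["region"],
    )


# ---------------------------------------------------------------------------
# response I/O

def _decode_frame(df: pd.DataFrame, inst: Instrument, register: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{source}: missing columns {missing}")
    df = df.copy()
    for col in ("facility_id", "round", "criterion_id"):
        df[col] = df[col].astype(str)
    for col, name in (("subtool", "subtool"), ("respondent", "respondent"), ("value", "value")):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise DataError(f"{source}: non-integer {name} column: {exc}") from exc

    legal = {int(v) for v in ResponseValue}
    bad = df.index[~df["value"].isin(legal)]
    if len(bad):
        i = bad[0]
        raise DataError(
            f"{source}, row {i + 2}: illegal value code {df.at[i, 'value']} "
            f"(expected 1=yes, 0=no, 99=NA)"
        )

    known = set(register["id"])
    bad = df.index[~df["facility_id"].isin(known)]
    if len(bad):
        i = bad[0]
        raise DataError(f"{source}, row {i + 2}: unknown facility id {df.at[i, 'facility_id']!r}")

    crit_subtool = inst.criterion_subtool()
    bad = df.index[~df["criterion_id"].isin(crit_subtool.keys())]
    if len(bad):
        i = bad[0]
        raise DataError(f"{source}, row {i + 2}: unknown criterion id {df.at[i, 'criterion_id']!r}")
    expected = df["criterion_id"].map(crit_subtool)
    bad = df.index[df["subtool"] != expected]
    if len(bad):
        i = bad[0]
        raise DataError(
            f"{source}, row {i + 2}: criterion {df.at[i, 'criterion_id']!r} belongs to "
            f"sub-tool {expected[i]}, row says {df.at[i, 'subtool']}"
        )
    if (df["respondent"] < 1).any():
        i = df.index[df["respondent"] < 1][0]
        raise DataError(f"{source}, row {i + 2}: respondent index must be >= 1")

    # respondent index must stay within the rule maximum for the facility type
    ftype = df["facility_id"].map(register["type"])
    for st in inst.subtools:
        for ft in FacilityType:
            cap = st.respondent_rule.max_for(ft)
            mask = (df["subtool"] == st.index) & (ftype == ft.value) & (df["respondent"] > cap)
            if mask.any():
                i = df.index[mask][0]
                raise DataError(
                    f"{source}, row {i + 2}: respondent {df.at[i, 'respondent']} exceeds the "
                    f"maximum of {cap} for sub-tool {st.index} at a {ft.value}"
                )

    dup = df.duplicated(subset=["facility_id", "round", "criterion_id", "respondent"])
    if dup.any():
        i = df.index[dup][0]
        raise DataError(
            f"{source}, row {i + 2}: duplicate answer for criterion "
            f"{df.at[i, 'criterion_id']!r}, respondent {df.at[i, 'respondent']}"
        )
    return df


def sessions_from_frame(
    df: pd.DataFrame,
    inst: Instrument,
    register: pd.DataFrame,
    scenarios: Optional[Mapping[tuple[str, str], Iterable[Scenario]]] = None,
    source: str = "<frame>",
) -> list[AssessmentSession]:
    """Group a validated long-format frame into sessions.

    ``scenarios`` maps (facility_id, round) to the scenario tags actually
    observed; when absent, a scenario counts as observed if any response row
    for one of its criteria exists (the best the raw file can tell us).
    """
    df = _decode_frame(df, inst, register, source)
    scenario_of = {c.id: c.scenario for _, c in inst.iter_criteria() if c.scenario is not None}
    sessions = []
    for (fid, rnd), grp in df.groupby(["facility_id", "round"], sort=True):
        if scenarios is not None and (fid, rnd) in scenarios:
            observed = frozenset(Scenario(s) for s in scenarios[(fid, rnd)])
        else:
            observed = frozenset(
                scenario_of[cid] for cid in grp["criterion_id"].unique() if cid in scenario_of
            )
        records = [
            ResponseRecord(
                facility_id=fid,
                round=rnd,
                subtool_index=int(r.subtool),
                criterion_id=r.criterion_id,
                respondent=int(r.respondent),
                value=ResponseValue(int(r.value)),
            )
            for r in grp.itertuples(index=False)
        ]
        sessions.append(
            AssessmentSession(
                facility_id=fid,
                round=rnd,
                records=records,
                scenario_observed=observed,
                facility_type=FacilityType(register.at[fid, "type"]),
            )
        )
    return sessions


def read_responses(
    path: str | Path,
    inst: Instrument,
    register: pd.DataFrame,
    sessions_path: Optional[str | Path] = None,
) -> list[AssessmentSession]:
    """Read a long-format response CSV into sessions grouped by facility × round.

    ``sessions_path`` optionally points to a session-metadata CSV with columns
    ``facility_id, round, scenarios_observed`` (semicolon-separated tags) so
    that "scenario observed but every criterion missing" survives the
    round-trip. Raises :class:`DataError` on any malformed row.
    """
    df = pd.read_csv(path, dtype=str)
    scenarios = None
    if sessions_path is not None:
        meta = pd.read_csv(sessions_path, dtype=str).fillna("")
        missing = [c for c in SESSION_COLUMNS if c not in meta.columns]
        if missing:
            raise DataError(f"session file {sessions_path}: missing columns {missing}")
        scenarios = {
            (r.facility_id, r.round): [
                Scenario(s) for s in str(r.scenarios_observed).split(";") if s
            ]
            for r in meta.itertuples(index=False)
        }
    return sessions_from_frame(df, inst, register, scenarios, source=str(path))


def write_responses(
    sessions: Sequence[AssessmentSession],
    path: str | Path,
    sessions_path: Optional[str | Path] = None,
) -> None:
    """Write sessions back to the long CSV (plus optional session metadata)."""
    frames = [s.to_frame() for s in sessions if s.records]
    if frames:
        out = pd.concat(frames, ignore_index=True)[RESPONSE_COLUMNS]
    else:
        out = pd.DataFrame(columns=RESPONSE_COLUMNS)
    out.to_csv(path, index=False)
    if sessions_path is not None:
        meta = pd.DataFrame(
            {
                "facility_id": [s.facility_id for s in sessions],
                "round": [s.round for s in sessions],
                "scenarios_observed": [
                    ";".join(sorted(t.value for t in s.scenario_observed)) for s in sessions
                ],
            }
        )
        meta.to_csv(sessions_path, index=False)


# ---------------------------------------------------------------------------
# validation

def validate_session(inst: Instrument, session: AssessmentSession) -> list[Issue]:
    """Completeness and consistency checks for one session.

    Mirrors the front end's behaviour in batch form:

    * ``MISSING_ANSWER`` — a respondent answered some criteria of a sub-tool
      but not others (unobserved-scenario criteria are exempt);
    * ``RESPONDENT_COUNT`` — fewer distinct respondents on a sub-tool than the
      respondent rule's minimum for the facility type;
    * ``SCENARIO_GAP`` — responses to criteria of a scenario that is not in
      ``scenario_observed``.

    An empty list means the session is clean. The check is idempotent and
    independent of record order.
    """
    issues: list[Issue] = []
    by_subtool: dict[int, dict[int, set[str]]] = {}
    answered_scenarios: set[Scenario] = set()
    scenario_rows: dict[Scenario, str] = {}
    scenario_of = {c.id: c.scenario for _, c in inst.iter_criteria()}

    for rec in session.records:
        by_subtool.setdefault(rec.subtool_index, {}).setdefault(rec.respondent, set()).add(
            rec.criterion_id
        )
        tag = scenario_of.get(rec.criterion_id)
        if tag is not None and tag not in answered_scenarios:
            answered_scenarios.add(tag)
            scenario_rows[tag] = rec.criterion_id

    for tag in sorted(answered_scenarios - set(session.scenario_observed), key=lambda t: t.value):
        issues.append(
            Issue(
                code=IssueCode.SCENARIO_GAP,
                facility_id=session.facility_id,
                round=session.round,
                subtool_index=3,
                criterion_id=scenario_rows[tag],
                message=f"responses present for scenario {tag.value!r} not recorded as observed",
            )
        )

    for st in sorted(inst.subtools, key=lambda s: s.index):
        expected = [
            c
            for c in st.criteria
            if c.scenario is None or c.scenario in session.scenario_observed
        ]
        respondents = by_subtool.get(st.index, {})
        if session.facility_type is not None:
            lo = st.respondent_rule.min_for(session.facility_type)
            if len(respondents) < lo:
                issues.append(
                    Issue(
                        code=IssueCode.RESPONDENT_COUNT,
                        facility_id=session.facility_id,
                        round=session.round,
                        subtool_index=st.index,
                        message=(
                            f"sub-tool {st.index}: {len(respondents)} respondent(s), "
                            f"minimum {lo} for a {FacilityType(session.facility_type).value}"
                        ),
                    )
                )
        for resp in sorted(respondents):
            answered = respondents[resp]
            for c in expected:
                if c.id not in answered:
                    issues.append(
                        Issue(
                            code=IssueCode.MISSING_ANSWER,
                            facility_id=session.facility_id,
                            round=session.round,
                            subtool_index=st.index,
                            criterion_id=c.id,
                            respondent=resp,
                            message=(
                                f"respondent {resp} answered other criteria of sub-tool "
                                f"{st.index} but not {c.id!r}"
                            ),
                        )
                    )
    return issues
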