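"""Standardised analyses over facility scores.

Mirrors the reporting back end of the assessment system: unweighted means by
facility, council, region or ownership category; per-criterion met/not-met
disaggregation (the green/red list shown to providers); historical trend
tables; and the per-facility summary sheet of strengths and weaknesses left
behind after a visit.

All means are unweighted arithmetic means over facility scores within the
stratum; a facility whose dimension is undefined drops out of that
dimension's mean only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .assessments import AssessmentSession
from .instrument import Instrument
from .scoring import FacilityScore, facility_score, _criterion_stats

__all__ = [
    "EmptyStratumError",
    "aggregate",
    "historical_trend_table",
    "criterion_report",
    "SummarySheet",
    "summary_sheet",
    "render_summary_sheet",
    "coverage_summary",
]

DIM_COLUMNS = [f"dim_{i}" for i in range(1, 7)]

LEVELS = ("facility", "council", "region")
STRATIFIERS = (None, "none", "ownership")


class EmptyStratumError(ValueError):
    """No facility scores fall in the requested stratum."""


def _scores_wide(scores: Sequence[FacilityScore], register: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for fs in scores:
        row = {
            "facility_id": fs.facility_id,
            "round": fs.round,
            "overall": fs.overall_percent,
            "n_dimensions_defined": fs.n_dimensions_defined,
        }
        for i in range(1, 7):
            row[f"dim_{i}"] = fs.percent(i)
        rows.append(row)
    wide = pd.DataFrame(rows)
    if wide.empty:
        return wide
    for col in ("council", "region", "ownership", "type"):
        wide[col] = wide["facility_id"].map(register[col])
    return wide


def aggregate(
    scores: Sequence[FacilityScore],
    register: pd.DataFrame,
    level: str = "council",
    stratifier: Optional[str] = None,
    round: Optional[str] = None,
) -> pd.DataFrame:
    """Unweighted per-dimension and overall means by stratum.

    ``level`` is one of facility/council/region; ``stratifier`` optionally
    splits each stratum by ownership category. Facilities with an undefined
    dimension are excluded from that dimension's mean only (pandas ``mean``
    skips NaN). Raises :class:`EmptyStratumError` when nothing matches.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected ownership or none")
    wide = _scores_wide(scores, register)
    if round is not None and not wide.empty:
        wide = wide[wide["round"] == round]
    if wide.empty:
        raise EmptyStratumError(f"no facility scores for level={level!r}, round={round!r}")
    keys = ["facility_id"] if level == "facility" else [level]
    keys = ["round"] + keys
    if stratifier == "ownership":
        keys.append("ownership")
    grouped = wide.groupby(keys, sort=True)
    out = grouped[DIM_COLUMNS + ["overall"]].mean()
    out["n_facilities"] = grouped.size()
    return out.reset_index()


def historical_trend_table(
    scores: Sequence[FacilityScore],
    register: pd.DataFrame,
    level: str = "council",
    round_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Long table of per-round means: one row per stratum × round × dimension.

    Each round's mean is taken over the facilities assessed in that round, so
    strata with changing facility sets stay comparable round by round.
    ``round_order`` fixes the row order (default: sorted labels).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    wide = _scores_wide(scores, register)
    if wide.empty:
        return pd.DataFrame(columns=["round", level, "dimension", "mean_percent", "n_facilities"])
    key = "facility_id" if level == "facility" else level
    long = wide.melt(
        id_vars=["round", key],
        value_vars=DIM_COLUMNS + ["overall"],
        var_name="dimension",
        value_name="percent",
    )
    long["dimension"] = long["dimension"].str.replace("dim_", "", regex=False)
    grp = long.groupby(["round", key, "dimension"], sort=False)["percent"]
    out = pd.DataFrame({"mean_percent": grp.mean(), "n_facilities": grp.count()}).reset_index()
    rounds = list(round_order) if round_order is not None else sorted(out["round"].unique())
    out["round"] = pd.Categorical(out["round"], categories=rounds, ordered=True)
    dims = [str(i) for i in range(1, 7)] + ["overall"]
    out["dimension"] = pd.Categorical(out["dimension"], categories=dims, ordered=True)
    return out.sort_values(["round", key, "dimension"]).reset_index(drop=True)


def criterion_report(
    inst: Instrument,
    sessions: Sequence[AssessmentSession],
    cutoff: float = 0.75,
) -> pd.DataFrame:
    """Per-criterion met/not-met disaggregation across facilities.

    A facility *meets* a criterion when its proportion met p_c is at least
    ``cutoff`` (default 0.75, aligned with the satisfactory threshold); the
    report gives, per criterion, the share of facilities with a defined p_c
    that met it, and a green/red flag at the same cutoff on that share.
    """
    all_ids = {c.id for _, c in inst.iter_criteria()}
    counts: dict[str, list[int]] = {cid: [0, 0] for cid in all_ids}
    for session in sessions:
        for cid, (yes, n) in _criterion_stats(session, all_ids).items():
            counts[cid][1] += 1
            if yes / n >= cutoff:
                counts[cid][0] += 1
    rows = []
    for st, c in inst.iter_criteria():
        met, n = counts[c.id]
        share = met / n if n else math.nan
        rows.append(
            {
                "subtool": st.index,
                "criterion_id": c.id,
                "weight": c.weight,
                "n_facilities": n,
                "share_met": share,
                "flag": ("met" if share >= cutoff else "not_met") if n else "undefined",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummarySheet:
    """Main observations per facility visit: strengths and weaknesses.

    Criteria are ranked by weighted attainment w_c·p_c (strengths) and
    weighted shortfall w_c·(1−p_c) (weaknesses); ties break by criterion id.
    """

    facility_id: str
    round: str
    dimension_percents: dict[int, float]
    strengths: list[tuple[str, float]]  # (criterion_id, w·p)
    weaknesses: list[tuple[str, float]]  # (criterion_id, w·(1−p))


def summary_sheet(inst: Instrument, session: AssessmentSession, k: int = 5) -> SummarySheet:
    """Rank a scored session's criteria into top-k strengths / bottom-k weaknesses."""
    fs = facility_score(inst, session)
    attain: list[tuple[str, float, float]] = []
    applicable_ids = {
        c.id
        for st in inst.subtools
        for c in st.criteria
        if c.scenario is None or c.scenario in session.scenario_observed
    }
    stats = _criterion_stats(session, applicable_ids)
    for st, c in inst.iter_criteria():
        if c.id in stats:
            yes, n = stats[c.id]
            p = yes / n
            attain.append((c.id, c.weight * p, c.weight * (1.0 - p)))
    strengths = sorted(attain, key=lambda t: (-t[1], t[0]))[:k]
    weaknesses = [
        t for t in sorted(attain, key=lambda t: (-t[2], t[0])) if t[2] > 0
    ][:k]
    return SummarySheet(
        facility_id=session.facility_id,
        round=session.round,
        dimension_percents={i: fs.percent(i) for i in sorted(fs.dimensions)},
        strengths=[(cid, s) for cid, s, _ in strengths],
        weaknesses=[(cid, w) for cid, _, w in weaknesses],
    )


def render_summary_sheet(sheet: SummarySheet, inst: Instrument, decimals: int = 1) -> str:
    """Plain-text rendering of the two-copy paper summary sheet."""
    lines = [
        f"Summary sheet — facility {sheet.facility_id}, round {sheet.round}",
        "",
        "Scores per quality dimension:",
    ]
    for idx, pct in sheet.dimension_percents.items():
        name = inst.subtool(idx).dimension_name
        val = "undefined" if math.isnan(pct) else f"{pct:.{decimals}f} %"
        lines.append(f"  {idx}. {name}: {val}")
    lines.append("")
    lines.append("Strengths (weighted attainment):")
    for cid, s in sheet.strengths:
        lines.append(f"  [+{s:.{decimals}f}] {cid}: {inst.criterion(cid).text}")
    lines.append("")
    lines.append("Weaknesses (weighted shortfall):")
    if not sheet.weaknesses:
        lines.append("  none — all answered criteria fully met")
    for cid, w in sheet.weaknesses:
        lines.append(f"  [-{w:.{decimals}f}] {cid}: {inst.criterion(cid).text}")
    return "\n".join(lines) + "\n"


def coverage_summary(
    register: pd.DataFrame, assessed_ids: Sequence[str] | set[str]
) -> dict[str, float]:
    """Register coverage accounting: how many facilities were assessed, by type.

    Returns total and assessed counts, assessed counts per facility type, and
    the percentage of registered facilities assessed.
    """
    assessed = register[register["id"].isin(set(assessed_ids))]
    out: dict[str, float] = {
        "n_facilities": int(len(register)),
        "n_assessed": int(len(assessed)),
        "percent_assessed": 100.0 * len(assessed) / len(register) if len(register) else math.nan,
    }
    for ftype, count in assessed["type"].value_counts().items():
        out[f"n_assessed_{ftype}"] = int(count)
    for ftype in ("dispensary", "health_center", "hospital_opd"):
        out.setdefault(f"n_assessed_{ftype}", 0)
    return out
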