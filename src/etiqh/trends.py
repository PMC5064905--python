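"""Longitudinal comparison of scores: paired t-tests over complete pairs.

A council's (or region's) improvement between a baseline round and a later
round is tested with the classic paired-samples t-test on the facilities
assessed in *both* rounds ("complete pairs", matched by stable facility id —
a facility keeps its identity even if it is upgraded, e.g. from dispensary to
health center, between rounds). With differences d_i = post_i − baseline_i,

    t = d̄ / (s_d / √n),   df = n − 1,

two-sided p from Student's t. Significance is annotated with the usual star
convention: * p < 0.05, ** p < 0.01, *** p < 0.001.

Degenerate inputs are handled explicitly rather than returned as NaN: when
every difference is identical and nonzero the statistic is infinite and p is
reported as 0 (below any machine floor); when every difference is exactly
zero, t = 0 and p = 1. Both set ``zero_variance=True`` on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assessments import AssessmentSession
from .scoring import FacilityScore

__all__ = [
    "TrendResult",
    "MatchedPairs",
    "TooFewPairsError",
    "stars",
    "paired_trend_test",
    "trend_tests_by_dimension",
    "match_pairs",
    "council_trend_table",
    "STAR_THRESHOLDS",
]

#: (threshold, annotation), strict less-than, checked smallest first.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class TooFewPairsError(ValueError):
    """Fewer than two complete pairs — the paired test is undefined."""


def stars(
    p_value: float, thresholds: Sequence[tuple[float, str]] = STAR_THRESHOLDS
) -> str:
    """Map a p-value to its significance annotation (strict thresholds)."""
    if math.isnan(p_value):
        return ""
    for cut, mark in sorted(thresholds):
        if p_value < cut:
            return mark
    return ""


@dataclass(frozen=True)
class TrendResult:
    """Paired baseline/post comparison of one score in one stratum."""

    stratum: Optional[str]
    dimension: str  # "overall" or "1".."6"
    n_pairs: int
    mean_baseline: float
    mean_post: float
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    stars: str
    zero_variance: bool = False


def paired_trend_test(
    baseline: Mapping[str, float],
    post: Mapping[str, float],
    dimension: str = "overall",
    stratum: Optional[str] = None,
    star_thresholds: Sequence[tuple[float, str]] = STAR_THRESHOLDS,
) -> TrendResult:
    """Paired t-test of ``post − baseline`` over complete facility pairs.

    ``baseline`` and ``post`` map facility id → score; only ids present in
    both with finite values enter the test. Two-sided p. Raises
    :class:`TooFewPairsError` below two pairs.
    """
    ids = sorted(
        fid
        for fid in set(baseline) & set(post)
        if not (math.isnan(baseline[fid]) or math.isnan(post[fid]))
    )
    n = len(ids)
    if n < 2:
        raise TooFewPairsError(f"{n} complete pair(s); need at least 2")
    b = np.array([baseline[fid] for fid in ids], dtype=float)
    a = np.array([post[fid] for fid in ids], dtype=float)
    d = a - b
    mean_d = float(d.mean())
    s_d = float(d.std(ddof=1))
    df = n - 1
    zero_var = s_d == 0.0
    if zero_var:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, mean_d)
            p = 0.0
    else:
        t = mean_d / (s_d / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TrendResult(
        stratum=stratum,
        dimension=dimension,
        n_pairs=n,
        mean_baseline=float(b.mean()),
        mean_post=float(a.mean()),
        mean_difference=mean_d,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        stars=stars(p, star_thresholds),
        zero_variance=zero_var,
    )


def _score_map(scores: Sequence[FacilityScore], dimension: str) -> dict[str, float]:
    if dimension == "overall":
        return {fs.facility_id: fs.overall_percent for fs in scores}
    idx = int(dimension)
    return {fs.facility_id: fs.percent(idx) for fs in scores}


def trend_tests_by_dimension(
    baseline_scores: Sequence[FacilityScore],
    post_scores: Sequence[FacilityScore],
    stratum: Optional[str] = None,
    dimensions: Sequence[str] = ("overall", "1", "2", "3", "4", "5", "6"),
    bonferroni: bool = False,
) -> list[TrendResult]:
    """Run the paired test on the overall score and each dimension.

    With ``bonferroni=True`` the p-values (and stars) are adjusted for the
    number of dimensions tested; the default matches the unadjusted
    presentation conventional for these reports.
    """
    results = []
    m = len(dimensions)
    for dim in dimensions:
        res = paired_trend_test(
            _score_map(baseline_scores, dim), _score_map(post_scores, dim),
            dimension=dim, stratum=stratum,
        )
        if bonferroni:
            p_adj = min(1.0, res.p_value * m)
            res = TrendResult(
                **{**res.__dict__, "p_value": p_adj, "stars": stars(p_adj)}
            )
        results.append(res)
    return results


@dataclass(frozen=True)
class MatchedPairs:
    """Facilities present in both rounds, plus the excluded remainders."""

    paired_ids: tuple[str, ...]
    baseline_only: tuple[str, ...]
    post_only: tuple[str, ...]


def match_pairs(
    register: pd.DataFrame,
    baseline_sessions: Sequence[AssessmentSession],
    post_sessions: Sequence[AssessmentSession],
) -> MatchedPairs:
    """Pair facilities across rounds by stable id.

    Matching ignores facility-type changes between rounds (an upgraded
    dispensary keeps its pair); facilities assessed in only one round are
    listed as excluded, not errors. Ids absent from the register are rejected.
    """
    known = set(register["id"])
    b_ids = {s.facility_id for s in baseline_sessions}
    p_ids = {s.facility_id for s in post_sessions}
    unknown = (b_ids | p_ids) - known
    if unknown:
        raise KeyError(f"session facility id(s) not in register: {sorted(unknown)[:5]}")
    return MatchedPairs(
        paired_ids=tuple(sorted(b_ids & p_ids)),
        baseline_only=tuple(sorted(b_ids - p_ids)),
        post_only=tuple(sorted(p_ids - b_ids)),
    )


def council_trend_table(
    scores: Sequence[FacilityScore],
    register: pd.DataFrame,
    round_order: Optional[Sequence[str]] = None,
    level: str = "council",
    decimals: int = 1,
) -> pd.DataFrame:
    """Report-shaped trend table: one row per stratum × round.

    Columns are the six dimension means, the overall mean, the number of
    facilities assessed, and — on post-baseline rows — the paired-test stars
    comparing that round's overall facility scores against the stratum's
    baseline (first) round over complete pairs. Baseline rows carry no stars.
    """
    from .aggregation import _scores_wide, DIM_COLUMNS  # shared tidy helper

    wide = _scores_wide(scores, register)
    if wide.empty:
        raise ValueError("no scores to tabulate")
    key = "facility_id" if level == "facility" else level
    rounds = list(round_order) if round_order is not None else sorted(wide["round"].unique())
    rows = []
    for stratum, grp in wide.groupby(key, sort=True):
        present = [r for r in rounds if (grp["round"] == r).any()]
        if not present:
            continue
        base_round = present[0]
        base_map = {
            r.facility_id: r.overall for r in grp[grp["round"] == base_round].itertuples()
        }
        for rnd in present:
            sub = grp[grp["round"] == rnd]
            row = {key: stratum, "round": rnd, "n": int(len(sub))}
            for i, col in enumerate(DIM_COLUMNS, start=1):
                row[f"tool_{i}"] = round(sub[col].mean(), decimals)
            row["mean"] = round(sub["overall"].mean(), decimals)
            mark = ""
            if rnd != base_round:
                post_map = {r.facility_id: r.overall for r in sub.itertuples()}
                try:
                    mark = paired_trend_test(base_map, post_map, stratum=str(stratum)).stars
                except TooFewPairsError:
                    mark = ""
            row["stars"] = mark
            rows.append(row)
    return pd.DataFrame(rows)
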