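"""Two-step weighted scoring: worked examples, oracle equivalence, invariants."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from etiqh.instrument import Scenario
from etiqh.scoring import (
    NoDefinedCriteriaError,
    ScenarioNotObservedError,
    classify,
    criterion_proportion,
    facility_score,
    scenario_score,
    scores_frame,
    subtool_score,
)

from conftest import build_session, brute_force_percent

# frozen expected values, computed with brute_force_percent (see conftest):
# standard 3.1 weights (3,3,4,4,4,4,4); yes on a,b,d -> 100*(3+3+4)/26
EXPECTED_WORKED = 100.0 * 10 / 26  # 38.4615...
# same but 3.1g NA: denominator 26-4=22
EXPECTED_WORKED_NA = 100.0 * 10 / 22  # 45.4545...

STD31 = {"3.1a": 3, "3.1b": 3, "3.1c": 4, "3.1d": 4, "3.1e": 4, "3.1f": 4, "3.1g": 4}


@pytest.mark.parametrize(
    "values, p, n, defined",
    [
        ([1, 1, 0], 2 / 3, 3, True),
        ([99, 99], math.nan, 0, False),
        ([1, 99, 0, 1], 2 / 3, 3, True),
        ([], math.nan, 0, False),
        ([0, 0], 0.0, 2, True),
    ],
)
def test_criterion_proportion(values, p, n, defined):
    """p_c = yes/(yes+no), NA excluded from both sides, undefined when empty."""
    cs = criterion_proportion(values, "c")
    assert cs.n_responses == n and cs.defined is defined
    if defined:
        assert cs.proportion_met == pytest.approx(p)
    else:
        assert math.isnan(cs.proportion_met)


def test_criterion_proportion_rejects_bad_code():
    with pytest.raises(ValueError, match="illegal"):
        criterion_proportion([1, 2])


def _session_31(demo_inst, answers):
    return build_session(demo_inst, answers, scenario_observed=[])


def test_worked_example_standard_31(demo_inst):
    """Single respondent, yes on 3.1a/b/d only -> 38.46 % of 26 points."""
    answers = {cid: [1 if cid in ("3.1a", "3.1b", "3.1d") else 0] for cid in STD31}
    sc = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    assert sc.percent == pytest.approx(EXPECTED_WORKED, abs=1e-9)
    assert round(sc.percent, 2) == 38.46
    assert sc.points_achievable == 26
    assert sc.points_achieved == pytest.approx(10.0)


def test_worked_example_with_na(demo_inst):
    """3.1g answered NA shrinks the denominator to 22 -> 45.45 %."""
    answers = {cid: [1 if cid in ("3.1a", "3.1b", "3.1d") else 0] for cid in STD31}
    answers["3.1g"] = [99]
    sc = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    assert sc.percent == pytest.approx(EXPECTED_WORKED_NA, abs=1e-9)
    assert round(sc.percent, 2) == 45.45
    assert sc.points_achievable == 22


def test_all_yes_is_100(demo_inst):
    answers = {cid: [1, 1] for cid in STD31}
    sc = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    assert sc.percent == pytest.approx(100.0)


def test_all_na_raises(demo_inst):
    answers = {cid: [99] for cid in STD31}
    with pytest.raises(NoDefinedCriteriaError):
        subtool_score(demo_inst, _session_31(demo_inst, answers), 3)


def test_unobserved_scenario_forced_na(demo_inst):
    """Stray answers to an unobserved scenario are excluded from both sums."""
    answers = {cid: [1] for cid in STD31}
    answers["3.2a"] = [0]  # under5 criterion answered, scenario NOT observed
    sc = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    assert sc.percent == pytest.approx(100.0)
    assert sc.points_achievable == 26


def test_observed_scenario_enters_denominator(demo_inst):
    answers = {cid: [1] for cid in STD31}
    answers["3.2a"] = [0]
    session = build_session(demo_inst, answers, scenario_observed=[Scenario.UNDER5_IMCI])
    sc = subtool_score(demo_inst, session, 3)
    assert sc.points_achievable == 30  # 26 + weight-4 scenario criterion
    assert sc.percent == pytest.approx(100.0 * 26 / 30)


# -- exhaustive oracle equivalence on small response sets ---------------------

def _enumerate_small_cases():
    """All answer patterns for <=4 criteria x <=3 respondents over a seeded
    sample; exhaustive over the 1-criterion and 2-criterion spaces."""
    cases = []
    codes = (0, 1, 99)
    ids = ["3.1a", "3.1b", "3.1c", "3.1d"]
    # exhaustive: 1..2 criteria, 1..2 respondents
    import itertools

    for n_crit in (1, 2):
        for n_resp in (1, 2):
            for combo in itertools.product(
                itertools.product(codes, repeat=n_resp), repeat=n_crit
            ):
                cases.append({ids[i]: list(vals) for i, vals in enumerate(combo)})
    # seeded sample of the larger spaces up to 4 criteria x 3 respondents
    rng = random.Random(20210901)
    for _ in range(400):
        n_crit = rng.randint(3, 4)
        n_resp = rng.randint(1, 3)
        cases.append(
            {ids[i]: [rng.choice(codes) for _ in range(n_resp)] for i in range(n_crit)}
        )
    return cases


def test_engine_matches_brute_force_oracle(demo_inst):
    weights = STD31
    for answers in _enumerate_small_cases():
        expected = None
        try:
            expected = brute_force_percent(
                {cid: (weights[cid], vals) for cid, vals in answers.items()}
            )
        except ZeroDivisionError:
            with pytest.raises(NoDefinedCriteriaError):
                subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
            continue
        sc = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
        assert sc.percent == pytest.approx(expected, abs=1e-12), answers


# -- property suites ----------------------------------------------------------

answer_sets = st.dictionaries(
    st.sampled_from(list(STD31)),
    st.lists(st.sampled_from([0, 1, 99]), min_size=1, max_size=3),
    min_size=1,
    max_size=7,
)


@settings(max_examples=250, derandomize=True)
@given(answers=answer_sets)
def test_bounds_and_oracle_property(demo_inst, answers):
    """percent in [0,100]; 0 iff all defined p_c = 0; matches the oracle."""
    try:
        sc = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    except NoDefinedCriteriaError:
        assert all(all(v == 99 for v in vals) for vals in answers.values())
        return
    assert 0.0 <= sc.percent <= 100.0
    expected = brute_force_percent(
        {cid: (STD31[cid], vals) for cid, vals in answers.items()}
    )
    assert sc.percent == pytest.approx(expected, abs=1e-12)
    if sc.percent == 0.0:
        assert all(1 not in vals for vals in answers.values())


@settings(max_examples=250, derandomize=True)
@given(answers=answer_sets, data=st.data())
def test_monotone_in_single_flip(demo_inst, answers, data):
    """Flipping one NO->YES never lowers the percent (and vice versa)."""
    flippable = [
        (cid, i) for cid, vals in answers.items() for i, v in enumerate(vals) if v in (0, 1)
    ]
    if not flippable:
        return
    cid, i = data.draw(st.sampled_from(flippable))
    before = subtool_score(demo_inst, _session_31(demo_inst, answers), 3).percent
    flipped = {k: list(v) for k, v in answers.items()}
    old = flipped[cid][i]
    flipped[cid][i] = 1 - old
    after = subtool_score(demo_inst, _session_31(demo_inst, flipped), 3).percent
    if old == 0:  # NO -> YES
        assert after >= before - 1e-12
    else:
        assert after <= before + 1e-12


@settings(max_examples=100, derandomize=True)
@given(answers=answer_sets, scale=st.integers(min_value=2, max_value=5))
def test_weight_scale_invariance(demo_inst, answers, scale):
    """Multiplying all weights by a constant leaves the percent unchanged."""
    try:
        base = brute_force_percent({c: (STD31[c], v) for c, v in answers.items()})
    except ZeroDivisionError:
        return
    scaled = brute_force_percent({c: (STD31[c] * scale, v) for c, v in answers.items()})
    engine = subtool_score(demo_inst, _session_31(demo_inst, answers), 3).percent
    assert engine == pytest.approx(base, abs=1e-12)
    assert scaled == pytest.approx(base, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(answers=answer_sets, seed=st.integers(min_value=0, max_value=2**16))
def test_respondent_permutation_invariance(demo_inst, answers, seed):
    try:
        before = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    except NoDefinedCriteriaError:
        return
    rng = random.Random(seed)
    permuted = {cid: rng.sample(vals, len(vals)) for cid, vals in answers.items()}
    after = subtool_score(demo_inst, _session_31(demo_inst, permuted), 3)
    assert after.percent == pytest.approx(before.percent, abs=1e-12)
    assert after.points_achievable == before.points_achievable


@settings(max_examples=100, derandomize=True)
@given(answers=answer_sets)
def test_na_contracts_denominator(demo_inst, answers):
    """Turning one whole criterion to all-NA removes its weight from the
    achievable points."""
    try:
        before = subtool_score(demo_inst, _session_31(demo_inst, answers), 3)
    except NoDefinedCriteriaError:
        return
    cid = sorted(answers)[0]
    masked = {k: ([99] * len(v) if k == cid else v) for k, v in answers.items()}
    defined_before = {
        c for c, v in answers.items() if any(x != 99 for x in v)
    }
    try:
        after = subtool_score(demo_inst, _session_31(demo_inst, masked), 3)
    except NoDefinedCriteriaError:
        assert defined_before <= {cid}
        return
    expected_drop = STD31[cid] if cid in defined_before else 0
    assert after.points_achievable == pytest.approx(
        before.points_achievable - expected_drop
    )


# -- facility and scenario level ---------------------------------------------

def test_facility_score_all_dimensions(demo_inst):
    answers = {
        c.id: [1] for stl in demo_inst.subtools for c in stl.criteria if c.scenario is None
    }
    fs = facility_score(demo_inst, build_session(demo_inst, answers, scenario_observed=[]))
    assert fs.overall_percent == pytest.approx(100.0)
    assert fs.n_dimensions_defined == 6


def test_facility_score_mean_of_printed_council_row():
    """Mean of a published per-dimension row reproduces its printed mean to
    within 0.1 rounding (82.1, 75.5, 87.4, 69.9, 49.2, 93.7 -> 76.3 vs 76.4)."""
    dims = [82.1, 75.5, 87.4, 69.9, 49.2, 93.7]
    mean = sum(dims) / 6
    assert round(mean, 1) == 76.3
    assert abs(mean - 76.4) <= 0.1 + 1e-9


def test_facility_score_undefined_dimension(demo_inst):
    """An all-NA dimension drops out; the mean covers defined dimensions only."""
    answers = {
        c.id: [1] for stl in demo_inst.subtools for c in stl.criteria if c.scenario is None
    }
    for cid in ("2.1a", "2.1b"):
        answers[cid] = [99]
    fs = facility_score(demo_inst, build_session(demo_inst, answers, scenario_observed=[]))
    assert fs.dimensions[2] is None
    assert fs.n_dimensions_defined == 5
    assert fs.overall_percent == pytest.approx(100.0)


def test_scenario_score(demo_inst):
    session = build_session(
        demo_inst, {"3.2a": [1, 0]}, scenario_observed=[Scenario.UNDER5_IMCI]
    )
    sc = scenario_score(demo_inst, session, Scenario.UNDER5_IMCI)
    assert sc.percent == pytest.approx(50.0)
    with pytest.raises(ScenarioNotObservedError):
        scenario_score(demo_inst, session, Scenario.TB_HIV)


def test_scenario_score_matches_oracle(demo_inst):
    session = build_session(
        demo_inst,
        {"3.2a": [1, 0, 1], "3.1a": [0]},
        scenario_observed=[Scenario.UNDER5_IMCI],
    )
    expected = brute_force_percent({"3.2a": (4, [1, 0, 1])})
    sc = scenario_score(demo_inst, session, "under5_imci")
    assert sc.percent == pytest.approx(expected)


# -- classification -----------------------------------------------------------

@pytest.mark.parametrize(
    "percent, label",
    [(74.9, "unsatisfactory"), (75.0, "satisfactory"), (93.7, "satisfactory"),
     (0.0, "unsatisfactory"), (100.0, "satisfactory")],
)
def test_classify_strict_below_threshold(percent, label):
    assert classify(percent) == label


def test_classify_custom_threshold_and_range():
    assert classify(79.9, threshold=80) == "unsatisfactory"
    with pytest.raises(ValueError):
        classify(101.0)


def test_scores_frame_shape(demo_inst):
    answers = {
        c.id: [1] for stl in demo_inst.subtools for c in stl.criteria if c.scenario is None
    }
    fs = facility_score(demo_inst, build_session(demo_inst, answers, scenario_observed=[]))
    frame = scores_frame([fs], decimals=1)
    assert list(frame["dimension"]) == ["1", "2", "3", "4", "5", "6", "overall"]
    assert (frame["percent"] == 100.0).all()
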