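# Methods

This note documents the scoring model, the design choices made where the
methodology leaves room, the synthetic-data model and what it does and does
not emulate, and the package's numerical conventions and limitations.

## Instrument model

An instrument is a fixed hierarchy: six sub-tools (quality dimensions), each
with one or more quality standards, each standard with weighted verification
criteria answered yes/no/NA. Weights are positive integers, by convention
1 (less important) to 5 (essential). Criteria of sub-tool 3 (direct
observation of clinical consultations) may carry one of four scenario tags:
`under5_imci`, `pregnant`, `fever_over5`, `tb_hiv`.

Instruments are YAML documents with a `schema_version` field; validation
rejects duplicate criterion ids, out-of-range weights, scenario tags outside
sub-tool 3, and anything other than exactly six sub-tools, naming the
offending element.

Two instruments ship with the package:

* **demo** — a compact instrument whose sub-tool 3 carries the published
  standard-3.1 weights (3, 3, 4, 4, 4, 4, 4); all worked examples trace
  through it.
* **reference** — a structurally faithful fixture with placeholder texts
  matching the e-TIQH's published per-dimension accounting: criterion counts
  (41, 17, 124, 33, 23, 6) and point maxima (117, 34, 477, 217, 66, 24),
  935 points in total. The published figures for sub-tool 4 (33 criteria,
  217 points) are unreachable under a strict 1–5 weighting (maximum 165), so
  the schema allows a per-instrument `max_weight` and the reference fixture
  sets it to 7, using weight runs 19×7 + 14×6 for that sub-tool. Ordinary
  instruments keep the default cap of 5, and a weight of 7 in such a file is
  a validation error. The 477 points of sub-tool 3 are split as 24 general
  criteria (93 points) plus 25 criteria (96 points) per scenario — the
  methodology does not publish this split, so the fixture documents its own.

### Respondent rules

The number of providers interviewed or consultations observed depends on the
facility tier. The published rules pin dispensaries (1–3 interviews for
sub-tools 2 and 5) and hospitals (10 provider interviews), and give 5–10
respondents for the motivation and satisfaction interviews; health-center
values in between are not fully specified. The defaults chosen here, per
sub-tool and facility type (min–max):

| sub-tool | dispensary | health center | hospital OPD |
|---|---|---|---|
| 1, 4 (facility checklists) | 1 | 1 | 1 |
| 2, 3 (provider interview / observation) | 1–3 | 3–10 | 10 |
| 5 (staff motivation) | 1–3 | 5–10 | 5–10 |
| 6 (exit interviews) | 5–10 | 5–10 | 5–10 |

Rules are data, not code: any instrument file can override them.

## Score calculation

Step 1 — criterion averaging over respondents r:

    p_c = #yes / (#yes + #no)

Explicit NA answers (wire code 99) are excluded from numerator and
denominator. A criterion with no yes/no answers at all is *undefined*.

Step 2 — weighting within a sub-tool, over defined criteria only:

    S_d = 100 · Σ_c w_c · p_c / Σ_c w_c

The denominator therefore contracts when criteria do not apply — the
behaviour implied by maximum points quoted "per respondent interviewed" and
"if all four clinical scenarios are observed". Criteria tagged with a
scenario not recorded as observed are force-treated as NA even if stray
answers exist. The overall facility score is the unweighted mean of the
defined dimension percentages; the number of defined dimensions is carried
alongside because the methodology is silent on partially assessed
facilities, and silently averaging 3 dimensions as if they were 6 would be
misleading.

Properties the test-suite enforces: percentages live in [0, 100] and equal
100 exactly when every defined criterion is fully met; flipping any single
no→yes never lowers a score; scaling all weights by a constant changes
nothing; respondent order changes nothing; an all-NA criterion removes
exactly its weight from the achievable points. On every small response
pattern (up to 4 criteria × 3 responses, enumerated exhaustively up to
respondent order) the engine agrees with an independent brute-force
enumeration to 1e-12.

Other conventions:

* **Missing vs NA.** A missing row is not an NA: scoring excludes both, but
  validation flags a missing answer (`MISSING_ANSWER`, mirroring the
  front end's bounce-back) while an explicit 99 is clean data. Which checks
  the original device ran beyond bounce-back is not published; the issue
  taxonomy here (`MISSING_ANSWER`, `RESPONDENT_COUNT`, `SCENARIO_GAP`) is the
  package's own.
* **Classification.** "Unsatisfactory" is *strictly* below the threshold
  (default 75 %); 75.0 itself is satisfactory.
* **Rounding.** Full precision internally; outputs round to one decimal by
  default (two where an example needs it), matching reporting practice.
* **No respondent weighting.** Every respondent/observation contributes
  equally to p_c.

## Aggregation and reporting

Means at council/region level are unweighted arithmetic means over facility
scores — no size weighting — and a facility with an undefined dimension
drops out of that dimension's mean only. Ownership stratification splits the
same means by category; the n-weighted recombination of stratum means equals
the unstratified mean (tested). Criterion-level disaggregation reports, per
criterion, the share of facilities whose p_c reaches a cutoff (default 0.75,
aligned with the satisfactory threshold) with a met/not-met flag — the batch
analogue of the green/red list assessors show providers. The summary sheet
ranks criteria by weighted attainment w·p (strengths) and weighted shortfall
w·(1−p) (weaknesses), ties broken by criterion id; the methodology names the
output but not the ranking rule, so this rule is the package's own.

## Trend testing

Baseline vs post-baseline comparison is a classic paired t-test on facility
scores over complete pairs, matched by stable facility id (surviving
facility-type upgrades). The statistic is computed in closed form,
`t = d̄/(s_d/√n)` with df = n−1 and a two-sided p from Student's t — the
implementation is explicit rather than delegated so the degenerate branches
have defined semantics: all differences identical and nonzero → t = ±∞,
p = 0; all differences exactly zero → t = 0, p = 1 (both flagged
`zero_variance`); fewer than two pairs is an error. The test-suite
cross-checks the non-degenerate path against `scipy.stats.ttest_rel`.
The test is two-sided (no sidedness is published for these comparisons).
Stars follow `* <0.05, ** <0.01, *** <0.001`, strict. With more than two
rounds, the trend table takes the stratum's first round as baseline and
stars every later round against it; intermediate rounds are thus reported
descriptively *and* tested against baseline. No multiple-testing correction
is applied by default, matching conventional presentation; a Bonferroni flag
(`trend_tests_by_dimension(..., bonferroni=True)`) adjusts across dimensions
for users who want it.

## Synthetic-data model

The generator's defaults define the study conditions for all tests:

* Facility counts per council and the ownership mix (public 0.70,
  faith-based 0.15, private 0.10, institutional 0.05 — a typical rural-
  district profile) are allocated by largest-remainder rounding, ties in
  enum order, assigned deterministically in id order.
* Every criterion × respondent answer in dimension d, round r is an
  independent Bernoulli draw: yes with probability `q_d + (r−1)·δ_d`,
  overridden by NA with probability `na_prob` (default 0.05). Baseline
  levels `q_d` default to (0.75, 0.55, 0.70, 0.70, 0.40, 0.85) — staff
  motivation lowest, client satisfaction highest, the qualitative ordering
  that baseline assessments of this kind consistently show — with per-round
  gains δ_d of (0.02, 0.05, 0.03, 0.03, 0.06, 0.01): the weakest dimensions
  improve fastest. The config validator enforces
  `q_d + (#rounds−1)·δ_d ≤ 1`.
* Respondent counts are drawn uniformly within the respondent rule's range;
  each scenario is observed with probability (0.95, 0.80, 0.90, 0.50 for
  under-5, pregnancy, fever, TB/HIV — TB/HIV presentations being the rarest
  in an outpatient day); unobserved scenarios emit no rows and are recorded
  in the session metadata.
* All draws derive from `numpy.random.SeedSequence(seed, round, facility)`,
  so a fixed seed gives byte-identical output files.

Because E[p_c] = q_d, the expected sub-tool percentage is 100·q_d
regardless of the weights, which is what makes parameter recovery a sharp
end-to-end check: scoring a 200-facility council generated at q = 0.6
returns a mean sub-tool percentage within ±1.5 points of 60.

What the default model does *not* emulate: facility-level quality
correlation (an optional beta-distributed per-facility effect,
`facility_effect_concentration`, adds it), criterion-level difficulty
differences, respondent-within-facility correlation, assessor effects, and
any real geography or naming. Passing tests on synthetic data therefore
demonstrate the *engine's* correctness and the test's statistical power
under known conditions — not that real councils behave like the model.

## Problem sizes used by the checks

The shipped verification runs use a 200-facility single-council register
(174 dispensaries, 20 health centers, 6 hospital OPDs — the tier mix of a
large rural district) for parameter recovery, 1,000 replicates of 40
complete pairs for the power of the paired test (true shift 5 points,
s_d = 5), and roughly 1.3 × 10⁵ exhaustively enumerated small response
patterns for oracle agreement. These sizes give Monte-Carlo error well
inside the stated tolerances.

## Known limitations

* No case-mix adjustment and no inter-rater reliability modelling; p_c
  treats all respondents as exchangeable.
* The paired t-test assumes approximately normal score differences;
  facility scores are bounded percentages, so very small strata with
  ceiling effects can violate this. Mixed-effects or interrupted
  time-series modelling is out of scope.
* The reference instrument's criterion texts are placeholders; analyses of
  real assessments require the council's own instrument file.
* Round labels are opaque ordered strings; calendar arithmetic (e.g.
  unequal spacing between rounds) is not modelled.
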