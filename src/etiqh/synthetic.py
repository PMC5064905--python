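"""Synthetic councils, registers, and multi-round response datasets.

The generator produces data in exactly the formats the rest of the package
reads (register CSV, long-format response CSV, session metadata), so every
stage of the pipeline is testable without field data. The response model is
deliberately simple and fully documented:

* every criterion × respondent answer in dimension *d* and round *r* is an
  independent Bernoulli draw, yes with probability ``q_d + (r−1)·δ_d``;
* with probability ``na_prob`` the answer is overridden by an explicit NA,
  emulating criteria that do not apply at a facility;
* respondent counts are drawn uniformly within the sub-tool's respondent-rule
  range for the facility type (a single observation for checklists);
* each of the four direct-observation scenarios is observed at a facility
  with its configured probability; criteria of unobserved scenarios produce
  no rows, and the session metadata records what was observed.

Dimension defaults mirror the qualitative structure seen in real baseline
assessments of this kind: staff motivation lowest, job expectations low,
client satisfaction high. An optional beta-distributed facility-level effect
adds between-facility heterogeneity; the default model is the independent
one.

Determinism: all draws derive from ``numpy.random.SeedSequence(seed, ...)``
keys, so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .assessments import (
    AssessmentSession,
    Ownership,
    ResponseRecord,
    ResponseValue,
    save_register,
    write_responses,
)
from .instrument import FacilityType, Instrument, Scenario

__all__ = [
    "CouncilConfig",
    "SyntheticConfig",
    "generate_register",
    "generate_round",
    "generate_dataset",
    "write_dataset",
]

OWNERSHIP_ORDER = [o for o in Ownership]


class CouncilConfig(BaseModel):
    name: str
    region: str
    n_dispensary: int = Field(ge=0, default=10)
    n_health_center: int = Field(ge=0, default=2)
    n_hospital: int = Field(ge=0, default=1)

    @property
    def n_total(self) -> int:
        return self.n_dispensary + self.n_health_center + self.n_hospital


class SyntheticConfig(BaseModel):
    """Every knob of the generator; see module docstring for the model."""

    model_config = ConfigDict(validate_assignment=True)

    councils: list[CouncilConfig] = Field(
        default_factory=lambda: [
            CouncilConfig(name="Council-A", region="Region-1"),
            CouncilConfig(name="Council-B", region="Region-1"),
        ]
    )
    #: ownership mix over (public, faith_based, private, institutional)
    ownership_mix: dict[Ownership, float] = Field(
        default_factory=lambda: {
            Ownership.PUBLIC: 0.70,
            Ownership.FAITH_BASED: 0.15,
            Ownership.PRIVATE: 0.10,
            Ownership.INSTITUTIONAL: 0.05,
        }
    )
    #: per-dimension baseline yes-probability; motivation lowest, satisfaction highest
    q: dict[int, float] = Field(
        default_factory=lambda: {1: 0.75, 2: 0.55, 3: 0.70, 4: 0.70, 5: 0.40, 6: 0.85}
    )
    #: per-dimension per-round improvement increment
    delta: dict[int, float] = Field(
        default_factory=lambda: {1: 0.02, 2: 0.05, 3: 0.03, 4: 0.03, 5: 0.06, 6: 0.01}
    )
    na_prob: float = 0.05
    scenario_probs: dict[Scenario, float] = Field(
        default_factory=lambda: {
            Scenario.UNDER5_IMCI: 0.95,
            Scenario.PREGNANT: 0.80,
            Scenario.FEVER_OVER5: 0.90,
            Scenario.TB_HIV: 0.50,
        }
    )
    rounds: list[str] = Field(default_factory=lambda: ["2011", "2012"])
    #: optional beta-concentration for a facility-level quality effect;
    #: None = independent model (the default)
    facility_effect_concentration: Optional[float] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name, probs in (
            ("ownership_mix", self.ownership_mix.values()),
            ("q", self.q.values()),
            ("delta", self.delta.values()),
            ("scenario_probs", self.scenario_probs.values()),
            ("na_prob", [self.na_prob]),
        ):
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}: probability {p} outside [0, 1]")
        if abs(sum(self.ownership_mix.values()) - 1.0) > 1e-9:
            raise ValueError("ownership_mix must sum to 1")
        if sorted(self.q) != [1, 2, 3, 4, 5, 6] or sorted(self.delta) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("q and delta must be keyed by sub-tool indices 1..6")
        if not self.rounds:
            raise ValueError("at least one round is required")
        n_rounds = len(self.rounds)
        for d in range(1, 7):
            top = self.q[d] + (n_rounds - 1) * self.delta[d]
            if top > 1.0 + 1e-9:
                raise ValueError(
                    f"dimension {d}: q + (rounds-1)*delta = {top:.3f} exceeds 1"
                )
        if self.facility_effect_concentration is not None and (
            self.facility_effect_concentration <= 0
        ):
            raise ValueError("facility_effect_concentration must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        doc = self.model_dump(mode="json")
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Integer allocation of ``total`` by largest remainder; ties by position."""
    exact = np.asarray(proportions, dtype=float) * total
    base = np.floor(exact).astype(int)
    short = total - int(base.sum())
    # stable sort: equal remainders resolve in listed (enum) order
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def generate_register(config: SyntheticConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Deterministic facility register matching the configured counts exactly.

    Ownership categories are allocated per council by largest-remainder
    rounding of the mix (ties in enum order) and assigned to facilities in id
    order, so the register is fully determined by the config; ``seed`` is
    accepted for interface symmetry but not needed.
    """
    del seed  # allocation is deterministic by design
    rows = []
    for council in config.councils:
        types = (
            [FacilityType.DISPENSARY] * council.n_dispensary
            + [FacilityType.HEALTH_CENTER] * council.n_health_center
            + [FacilityType.HOSPITAL_OPD] * council.n_hospital
        )
        mix = [config.ownership_mix.get(o, 0.0) for o in OWNERSHIP_ORDER]
        counts = _largest_remainder(mix, len(types))
        owners: list[Ownership] = []
        for o, c in zip(OWNERSHIP_ORDER, counts):
            owners.extend([o] * c)
        for i, (ftype, owner) in enumerate(zip(types, owners), start=1):
            fid = f"{council.name}-F{i:03d}"
            rows.append(
                {
                    "id": fid,
                    "name": f"Facility {i:03d} ({council.name})",
                    "type": ftype.value,
                    "ownership": owner.value,
                    "council": council.name,
                    "region": council.region,
                }
            )
    return pd.DataFrame(rows, columns=["id", "name", "type", "ownership", "council", "region"]).set_index(
        "id", drop=False
    )


def _facility_q(
    base_q: float, rng: np.random.Generator, concentration: Optional[float]
) -> float:
    if concentration is None or base_q in (0.0, 1.0):
        return base_q
    a = base_q * concentration
    b = (1.0 - base_q) * concentration
    return float(rng.beta(a, b))


def generate_round(
    inst: Instrument,
    register: pd.DataFrame,
    config: SyntheticConfig,
    round_label: str,
    seed: Optional[int] = None,
) -> list[AssessmentSession]:
    """Simulate one assessment round for every facility in the register.

    ``round_label`` must be one of ``config.rounds``; the yes-probability for
    dimension d is ``q_d + (round_index)·δ_d`` with the first configured round
    as baseline. Seeds are derived per facility from
    ``SeedSequence(seed, round_index, facility_position)``.
    """
    if round_label not in config.rounds:
        raise ValueError(f"round {round_label!r} not in configured rounds {config.rounds}")
    r_idx = config.rounds.index(round_label)
    base_seed = config.seed if seed is None else seed

    crit_by_subtool: dict[int, list] = {
        st.index: list(st.criteria) for st in inst.subtools
    }
    sessions: list[AssessmentSession] = []
    for f_pos, fac in enumerate(register.itertuples(index=False)):
        rng = np.random.default_rng(np.random.SeedSequence((base_seed, r_idx, f_pos)))
        ftype = FacilityType(fac.type)
        observed = frozenset(
            tag for tag in Scenario if rng.random() < config.scenario_probs.get(tag, 0.0)
        )
        records: list[ResponseRecord] = []
        for st in sorted(inst.subtools, key=lambda s: s.index):
            p_yes = min(1.0, config.q[st.index] + r_idx * config.delta[st.index])
            p_yes = _facility_q(p_yes, rng, config.facility_effect_concentration)
            lo, hi = st.respondent_rule.range_for(ftype)
            n_resp = int(rng.integers(lo, hi + 1))
            criteria = [
                c
                for c in crit_by_subtool[st.index]
                if c.scenario is None or c.scenario in observed
            ]
            if not criteria:
                continue
            shape = (len(criteria), n_resp)
            yes = rng.random(shape) < p_yes
            na = rng.random(shape) < config.na_prob
            for ci, crit in enumerate(criteria):
                for resp in range(1, n_resp + 1):
                    if na[ci, resp - 1]:
                        value = ResponseValue.NA
                    else:
                        value = ResponseValue.YES if yes[ci, resp - 1] else ResponseValue.NO
                    records.append(
                        ResponseRecord(
                            facility_id=fac.id,
                            round=round_label,
                            subtool_index=st.index,
                            criterion_id=crit.id,
                            respondent=resp,
                            value=value,
                        )
                    )
        sessions.append(
            AssessmentSession(
                facility_id=fac.id,
                round=round_label,
                records=records,
                scenario_observed=observed,
                facility_type=ftype,
            )
        )
    return sessions


def generate_dataset(
    inst: Instrument, config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, list[AssessmentSession]]:
    """Register plus sessions for every configured round."""
    register = generate_register(config)
    sessions: list[AssessmentSession] = []
    for rnd in config.rounds:
        sessions.extend(generate_round(inst, register, config, rnd, seed=seed))
    return register, sessions


def write_dataset(
    inst: Instrument,
    config: SyntheticConfig,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Generate and write register.csv, responses.csv, sessions.csv, scenario.yaml.

    Identical (config, seed) pairs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    register, sessions = generate_dataset(inst, config, seed=seed)
    paths = {
        "register": out / "register.csv",
        "responses": out / "responses.csv",
        "sessions": out / "sessions.csv",
        "config": out / "scenario.yaml",
    }
    save_register(register, paths["register"])
    write_responses(sessions, paths["responses"], sessions_path=paths["sessions"])
    config.to_yaml(paths["config"])
    return paths
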