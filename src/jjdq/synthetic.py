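"""Labelled synthetic CMS extracts with ground-truth error injection.

Real juvenile-justice case-management extracts are confidential, so tests
and demonstrations run on synthetic ones. The generator emulates their
shape: four CMS vendors across twelve counties, multiple arrests per youth,
demographic marginals resembling published county caseloads, and seven
tri-state decision-point fields filled from rule-free case *trajectories*:

* ``DIVERSION_TERMINAL`` — diverted yes; petitioned…waived no;
* ``PETITION_PATH``      — petitioned and adjudicated yes, one disposition
  (probation or confinement) yes;
* ``WAIVER_TERMINAL``    — petitioned yes, adjudicated no, waived yes;
* ``NOT_TRUE_PATH``      — petitioned yes, adjudication found not true;

detention is drawn independently (it is order-exempt and rule-free).

Corruption happens in three labelled layers:

1. **missingness** — an i.i.d. per-(case, point) mask at configured rates,
   drawn first and never altered, so per-point completeness marginals are
   exactly binomial;
2. **rule injection** — disjoint case subsets (one rule per corrupted case,
   quota = round(rate x n)) receive a minimal field corruption that makes
   exactly the injected rule fire, with the injected resolution scenario as
   its exact inverse; cases whose mask covers a needed pattern field are
   skipped in favour of mask-compatible ones, which keeps detector recall
   exact without biasing the mask;
3. **conformance noise** — raw tokens outside the yes/no/missing vocabulary,
   written per decision-point field at a configured rate (pattern-pinned
   fields of injected cases exempt).

Every corruption is recorded in a :class:`SyntheticTruth` so tests can score
detector recall and first-error attribution exactly.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field as dc_field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .cleaning import Strategy
from .errors import ConfigError, InjectionError
from .records import (
    CMS_IDS,
    CaseRecord,
    DecisionPoint,
    Extract,
    Phase,
    ResponseValue,
    parse_rows,
)
from .rules import RuleId

__all__ = [
    "Trajectory",
    "GeneratorConfig",
    "CaseTruth",
    "SyntheticTruth",
    "sample_trajectory",
    "inject",
    "generate",
    "NONCONFORMING_TOKENS",
]

YES = ResponseValue.YES
NO = ResponseValue.NO
MISSING = ResponseValue.MISSING
D = DecisionPoint

#: Raw tokens used for conformance noise; content is irrelevant, only
#: non-membership in the yes/no/missing vocabulary matters.
NONCONFORMING_TOKENS = ("unknown", "TRUE", "y")


class Trajectory(Enum):
    DIVERSION_TERMINAL = "diversion_terminal"
    PETITION_PATH = "petition_path"
    WAIVER_TERMINAL = "waiver_terminal"
    NOT_TRUE_PATH = "not_true_path"

    def __repr__(self) -> str:
        return self.name


def _default_cms_mix() -> dict[str, float]:
    # relative caseload of the four systems (one dominant vendor)
    return {"CMS1": 0.092, "CMS2": 0.054, "CMS3": 0.791, "CMS4": 0.063}


def _default_demographics() -> dict[str, dict]:
    return {
        "gender": {"male": 0.66, "female": 0.34},
        "race_ethnicity": {
            "White": 0.60,
            "African American/Black": 0.25,
            "Hispanic/Latino": 0.05,
            "Other": 0.07,
            "Asian": 0.01,
            "Native American or Native Alaskan": 0.01,
            "Hawaiian/Pacific Islander": 0.01,
        },
        # ages 10-18, mean ~15.2
        "age": {10: 0.010, 11: 0.018, 12: 0.040, 13: 0.085, 14: 0.140,
                15: 0.195, 16: 0.250, 17: 0.250, 18: 0.012},
        "charge_severity": {
            "Felony A": 0.005, "Felony B": 0.02, "Felony C": 0.025, "Felony D": 0.15,
            "Misdemeanor A": 0.25, "Misdemeanor B": 0.13, "Misdemeanor C": 0.05,
            "Status Offense": 0.20, "Violation of Probation": 0.17,
        },
    }


def _default_trajectory_mix() -> dict[Trajectory, float]:
    return {
        Trajectory.DIVERSION_TERMINAL: 0.35,
        Trajectory.PETITION_PATH: 0.45,
        Trajectory.WAIVER_TERMINAL: 0.02,
        Trajectory.NOT_TRUE_PATH: 0.18,
    }


def _default_scenario_mix() -> dict[RuleId, dict[Strategy, float]]:
    # FIX_DIVERSION is selectable but off by default: its corrupted case
    # carries petitioned=missing (see _spec_for), which perturbs the
    # completeness marginal of that point.
    return {
        RuleId.INCONSISTENT_PETITION: {Strategy.OVERTURNED: 0.5, Strategy.VIOLATED_AGREEMENT: 0.5},
        RuleId.IMPLAUSIBLE_CASE: {Strategy.COURTESY_DETENTION: 0.5, Strategy.CLERICAL: 0.5},
        RuleId.EXCESS_INFORMATION: {Strategy.UNLINK: 1.0},
        RuleId.INCONSISTENT_WAIVER: {Strategy.FIX: 1.0},
        RuleId.INCONSISTENT_ADJUDICATION: {Strategy.BACKFILL: 1.0},
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic extract generator (all rates in [0, 1])."""

    n_youth: int = 800
    arrests_per_youth_mean: float = 1.3
    cms_mix: dict[str, float] = dc_field(default_factory=_default_cms_mix)
    demographic_marginals: dict[str, dict] = dc_field(default_factory=_default_demographics)
    trajectory_mix: dict[Trajectory, float] = dc_field(default_factory=_default_trajectory_mix)
    detention_prob: float = 0.3
    missingness_rates: dict[DecisionPoint, float] = dc_field(
        default_factory=lambda: {p: 0.0 for p in DecisionPoint}
    )
    injection_rates: dict[RuleId, float] = dc_field(
        default_factory=lambda: {r: 0.0 for r in RuleId}
    )
    scenario_mix: dict[RuleId, dict[Strategy, float]] = dc_field(
        default_factory=_default_scenario_mix
    )
    conformance_noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_youth < 1:
            problems.append("n_youth must be >= 1")
        if self.arrests_per_youth_mean < 1.0:
            problems.append("arrests_per_youth_mean must be >= 1 (every youth has one arrest)")
        for name, vec in [
            ("cms_mix", self.cms_mix),
            ("trajectory_mix", self.trajectory_mix),
            *[(f"demographic_marginals.{k}", v) for k, v in self.demographic_marginals.items()],
        ]:
            total = sum(vec.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                problems.append(f"{name} sums to {total!r}, not 1")
            if any(p < 0 for p in vec.values()):
                problems.append(f"{name} has a negative probability")
        for name, rates in [
            ("missingness_rates", self.missingness_rates),
            ("injection_rates", self.injection_rates),
        ]:
            for key, rate in rates.items():
                if not 0.0 <= rate <= 1.0:
                    problems.append(f"{name}[{getattr(key, 'name', key)}] = {rate!r} outside [0, 1]")
        if sum(self.injection_rates.values()) > 1.0 + 1e-9:
            problems.append("injection_rates sum exceeds 1 (subsets must be disjoint)")
        if not 0.0 <= self.detention_prob <= 1.0:
            problems.append("detention_prob outside [0, 1]")
        if not 0.0 <= self.conformance_noise_rate <= 1.0:
            problems.append("conformance_noise_rate outside [0, 1]")
        unknown_cms = set(self.cms_mix) - set(CMS_IDS)
        if unknown_cms:
            problems.append(f"cms_mix has unknown CMS labels {sorted(unknown_cms)}")
        for rule, mix in self.scenario_mix.items():
            if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
                problems.append(f"scenario_mix[{rule.name}] does not sum to 1")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs: dict = {}
        for key in ("n_youth", "arrests_per_youth_mean", "detention_prob",
                    "conformance_noise_rate", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cms_mix" in raw:
            kwargs["cms_mix"] = {str(k): float(v) for k, v in raw["cms_mix"].items()}
        if "demographic_marginals" in raw:
            margins = {}
            for dim, vec in raw["demographic_marginals"].items():
                caster = int if dim == "age" else str
                margins[dim] = {caster(k): float(v) for k, v in vec.items()}
            kwargs["demographic_marginals"] = margins
        if "trajectory_mix" in raw:
            kwargs["trajectory_mix"] = {
                Trajectory[k]: float(v) for k, v in raw["trajectory_mix"].items()
            }
        if "missingness_rates" in raw:
            kwargs["missingness_rates"] = {
                DecisionPoint[k]: float(v) for k, v in raw["missingness_rates"].items()
            }
        if "injection_rates" in raw:
            kwargs["injection_rates"] = {
                RuleId[k]: float(v) for k, v in raw["injection_rates"].items()
            }
        if "scenario_mix" in raw:
            kwargs["scenario_mix"] = {
                RuleId[r]: {Strategy[s]: float(v) for s, v in mix.items()}
                for r, mix in raw["scenario_mix"].items()
            }
        config = cls(**kwargs)
        # unspecified per-point / per-rule rates default to 0
        config.missingness_rates = {p: config.missingness_rates.get(p, 0.0) for p in DecisionPoint}
        config.injection_rates = {r: config.injection_rates.get(r, 0.0) for r in RuleId}
        return config


@dataclass
class CaseTruth:
    """Ground-truth corruption labels for one case."""

    injected_rule: RuleId | None = None
    injected_scenario: Strategy | None = None
    injected_missing: frozenset[DecisionPoint] = frozenset()
    injected_nonconforming: frozenset[tuple[str, str]] = frozenset()
    original: CaseRecord | None = None  # pre-corruption record (rule-injected cases)


@dataclass
class SyntheticTruth:
    """Everything the generator did, keyed by case, plus bookkeeping tallies."""

    per_case: dict[str, CaseTruth] = dc_field(default_factory=dict)
    youth_case_counts: dict[str, int] = dc_field(default_factory=dict)
    demographic_counts: dict[str, dict[str, dict]] = dc_field(default_factory=dict)

    def injected_cases(self, rule: RuleId | None = None) -> list[str]:
        return [
            cid
            for cid, t in self.per_case.items()
            if t.injected_rule is not None and (rule is None or t.injected_rule is rule)
        ]

    def to_json(self, path: str | Path | io.TextIOBase) -> None:
        payload = {
            "per_case": {
                cid: {
                    "injected_rule": t.injected_rule.name if t.injected_rule else None,
                    "injected_scenario": t.injected_scenario.name if t.injected_scenario else None,
                    "injected_missing": sorted(p.name for p in t.injected_missing),
                    "injected_nonconforming": sorted(list(x) for x in t.injected_nonconforming),
                }
                for cid, t in self.per_case.items()
            },
            "youth_case_counts": self.youth_case_counts,
        }
        if isinstance(path, (str, Path)):
            with open(path, "w", encoding="utf-8") as handle:
                json.dump(payload, handle, indent=1, sort_keys=True)
        else:
            json.dump(payload, path, indent=1, sort_keys=True)


def sample_trajectory(
    kind: Trajectory, detained: bool, rng: np.random.Generator
) -> dict[DecisionPoint, ResponseValue]:
    """A rule-free decision-point assignment for one case.

    The templates are fixed a priori from the meaning of each path through
    the system, not derived from the rule engine, so the clean-by-construction
    property is an independent check of both.
    """
    points = {p: NO for p in DecisionPoint}
    if kind is Trajectory.DIVERSION_TERMINAL:
        points[D.DIVERTED] = YES
    elif kind is Trajectory.PETITION_PATH:
        points[D.PETITIONED] = YES
        points[D.ADJUDICATED] = YES
        disposition = D.PROBATION if rng.random() < 0.5 else D.CONFINED
        points[disposition] = YES
    elif kind is Trajectory.WAIVER_TERMINAL:
        points[D.PETITIONED] = YES
        points[D.WAIVED] = YES
    elif kind is Trajectory.NOT_TRUE_PATH:
        points[D.PETITIONED] = YES
    else:  # pragma: no cover - exhaustive enum
        raise InjectionError(f"unknown trajectory kind {kind!r}")
    points[D.DETAINED] = YES if detained else NO
    return points


# ---------------------------------------------------------------------------
# rule injection
#
# Each (rule, scenario) corruption is built from a base trajectory plus two
# update layers:
#   original_updates  — adjustments to the pre-corruption record so that the
#                       scenario's cleaning strategy inverts the corruption
#                       field-for-field (e.g. UNLINK restores MISSING, so the
#                       original already carries MISSING there);
#   corrupted_updates — the corruption itself.
# ``pattern`` lists fields that must stay unmasked (and free of conformance
# noise) for the rule to fire and the first error to attribute correctly.

_SUBSEQUENT = (D.ADJUDICATED, D.PROBATION, D.CONFINED, D.WAIVED)
_DISPOSITIONS = (D.PROBATION, D.CONFINED)


@dataclass(frozen=True)
class _InjectionSpec:
    base: Trajectory
    pattern: tuple[DecisionPoint, ...]
    original_updates: dict[DecisionPoint, ResponseValue]
    corrupted_updates: dict[DecisionPoint, ResponseValue]


def scenario_compatible(
    rule: RuleId, scenario: Strategy, mask: frozenset[DecisionPoint]
) -> bool:
    """Whether a (rule, scenario) corruption survives this missingness mask."""
    if (rule, scenario) not in _SCENARIO_BASES:
        return False
    if rule is RuleId.EXCESS_INFORMATION and scenario is Strategy.UNLINK:
        return D.DIVERTED not in mask and any(q not in mask for q in _SUBSEQUENT)
    if rule is RuleId.EXCESS_INFORMATION and scenario is Strategy.FIX_DIVERSION:
        return D.DIVERTED not in mask and D.ADJUDICATED not in mask
    if rule is RuleId.INCONSISTENT_WAIVER:
        return D.WAIVED not in mask and D.ADJUDICATED not in mask
    if rule is RuleId.INCONSISTENT_ADJUDICATION:
        return D.ADJUDICATED not in mask and any(q not in mask for q in _DISPOSITIONS)
    # the two petition-anchored rules need both anchor fields
    return D.DIVERTED not in mask and D.PETITIONED not in mask


_SCENARIO_BASES: dict[tuple[RuleId, Strategy], Trajectory] = {
    (RuleId.INCONSISTENT_PETITION, Strategy.OVERTURNED): Trajectory.PETITION_PATH,
    (RuleId.INCONSISTENT_PETITION, Strategy.VIOLATED_AGREEMENT): Trajectory.DIVERSION_TERMINAL,
    (RuleId.IMPLAUSIBLE_CASE, Strategy.COURTESY_DETENTION): Trajectory.NOT_TRUE_PATH,
    (RuleId.IMPLAUSIBLE_CASE, Strategy.CLERICAL): Trajectory.NOT_TRUE_PATH,
    (RuleId.EXCESS_INFORMATION, Strategy.UNLINK): Trajectory.DIVERSION_TERMINAL,
    (RuleId.EXCESS_INFORMATION, Strategy.FIX_DIVERSION): Trajectory.PETITION_PATH,
    (RuleId.INCONSISTENT_WAIVER, Strategy.FIX): Trajectory.WAIVER_TERMINAL,
    (RuleId.INCONSISTENT_ADJUDICATION, Strategy.BACKFILL): Trajectory.PETITION_PATH,
}


def _spec_for(
    rule: RuleId,
    scenario: Strategy,
    rng: np.random.Generator,
    mask: frozenset[DecisionPoint],
) -> _InjectionSpec:
    base = _SCENARIO_BASES[(rule, scenario)]
    if rule is RuleId.INCONSISTENT_PETITION and scenario is Strategy.OVERTURNED:
        return _InjectionSpec(base, (D.DIVERTED, D.PETITIONED), {}, {D.DIVERTED: YES})
    if rule is RuleId.INCONSISTENT_PETITION and scenario is Strategy.VIOLATED_AGREEMENT:
        return _InjectionSpec(base, (D.DIVERTED, D.PETITIONED), {}, {D.PETITIONED: YES})
    if rule is RuleId.IMPLAUSIBLE_CASE:
        return _InjectionSpec(base, (D.DIVERTED, D.PETITIONED), {}, {D.PETITIONED: NO})
    if rule is RuleId.EXCESS_INFORMATION and scenario is Strategy.UNLINK:
        # a later arrest's outcome got linked onto a diversion; the true
        # value of that field for THIS arrest is unknowable, so the original
        # already carries MISSING there — exactly what UNLINK restores.
        candidates = [q for q in _SUBSEQUENT if q not in mask]
        offending = candidates[int(rng.integers(len(candidates)))]
        return _InjectionSpec(
            base, (D.DIVERTED, offending), {offending: MISSING}, {offending: YES}
        )
    if rule is RuleId.EXCESS_INFORMATION and scenario is Strategy.FIX_DIVERSION:
        # diversion field wrongly filled on a petitioned case. The original
        # keeps petitioned=missing: yes would hand the corrupted case to the
        # inconsistent-petition rule, no would leave the resolved case
        # implausible.
        return _InjectionSpec(
            base, (D.DIVERTED, D.ADJUDICATED), {D.PETITIONED: MISSING}, {D.DIVERTED: YES}
        )
    if rule is RuleId.INCONSISTENT_WAIVER:
        # flips adjudicated, not a disposition: a stray probation/confinement
        # yes would fire the adjudication rule at an earlier anchor and steal
        # the first-error attribution.
        return _InjectionSpec(base, (D.WAIVED, D.ADJUDICATED), {}, {D.ADJUDICATED: YES})
    if rule is RuleId.INCONSISTENT_ADJUDICATION:
        candidates = [q for q in _DISPOSITIONS if q not in mask]
        disposition = candidates[int(rng.integers(len(candidates)))]
        other = D.CONFINED if disposition is D.PROBATION else D.PROBATION
        original_updates = {disposition: YES}
        if other not in mask:  # pin the base's coin-flipped disposition
            original_updates[other] = NO
        return _InjectionSpec(
            base, (D.ADJUDICATED, disposition), original_updates, {D.ADJUDICATED: NO}
        )
    raise InjectionError(f"scenario {scenario.name} does not inject rule {rule.name}")


def inject(
    case: CaseRecord,
    rule: RuleId,
    scenario: Strategy,
    rng: np.random.Generator,
    mask: frozenset[DecisionPoint] = frozenset(),
) -> tuple[CaseRecord, CaseRecord]:
    """Corrupt a rule-free case so that exactly ``rule`` fires first.

    Returns ``(original, corrupted)``. The corrupted case fires the rule
    under detection, and resolving it with ``scenario`` restores ``original``
    field-for-field (the injector may adjust fields of the original — e.g.
    set one MISSING — so corruption and resolution are exact inverses). The
    case's decision points are rebuilt from the scenario's base trajectory;
    ``mask`` marks points recorded as missing, which the pattern avoids.
    """
    if (rule, scenario) not in _SCENARIO_BASES:
        raise InjectionError(f"scenario {scenario.name} does not inject rule {rule.name}")
    if not scenario_compatible(rule, scenario, mask):
        raise InjectionError(
            f"mask {sorted(p.name for p in mask)} blocks {rule.name}/{scenario.name}"
        )
    spec = _spec_for(rule, scenario, rng, mask)
    base_points = sample_trajectory(spec.base, case.points[D.DETAINED] is YES, rng)
    masked = {p: (MISSING if p in mask else base_points[p]) for p in DecisionPoint}
    original_points = {**masked, **spec.original_updates}
    corrupted_points = {**original_points, **spec.corrupted_updates}
    original = replace(case, points=original_points)
    corrupted = replace(case, points=corrupted_points)
    return original, corrupted


def pattern_points(rule: RuleId, corrupted: CaseRecord) -> frozenset[DecisionPoint]:
    """Fields conformance noise must not touch for the rule to keep firing."""
    if rule is RuleId.EXCESS_INFORMATION:
        offenders = [q for q in _SUBSEQUENT if corrupted.points[q] is YES]
        return frozenset({D.DIVERTED, D.PETITIONED, *offenders})
    if rule is RuleId.INCONSISTENT_WAIVER:
        return frozenset({D.WAIVED, D.ADJUDICATED})
    if rule is RuleId.INCONSISTENT_ADJUDICATION:
        offenders = [q for q in _DISPOSITIONS if corrupted.points[q] is YES]
        return frozenset({D.ADJUDICATED, *offenders})
    return frozenset({D.DIVERTED, D.PETITIONED})


def _choice(rng: np.random.Generator, items: list, probs: list[float]):
    total = sum(probs)
    idx = rng.choice(len(items), p=[p / total for p in probs])
    return items[int(idx)]


def _raw_row(rec: CaseRecord, point_tokens: dict[DecisionPoint, str]) -> dict[str, str]:
    row = {
        "case_id": rec.case_id,
        "youth_id": rec.youth_id,
        "cms_id": rec.cms_id,
        "county_id": rec.county_id,
        "extraction_phase": rec.extraction_phase.value,
        "gender": rec.gender or "",
        "race_ethnicity": rec.race_ethnicity or "",
        "age": "" if rec.age_years is None else str(rec.age_years),
        "charge_severity": rec.charge_severity or "",
    }
    for p in DecisionPoint:
        row[p.column] = point_tokens.get(p, rec.points[p].value)
    return row


def generate(config: GeneratorConfig) -> tuple[Extract, SyntheticTruth]:
    """Generate one labelled synthetic extract (PRE phase).

    Deterministic for a fixed config (including seed). Rule injections are
    assigned to disjoint case subsets with per-rule quota round(rate x n);
    the missingness mask is drawn first and never altered, so per-point
    completeness marginals are unbiased by injection.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()

    cms_labels = sorted(config.cms_mix)
    cms_probs = [config.cms_mix[c] for c in cms_labels]
    margins = config.demographic_marginals
    traj_kinds = sorted(config.trajectory_mix, key=lambda t: t.name)
    traj_probs = [config.trajectory_mix[t] for t in traj_kinds]

    # --- youths and their cases (demographics are youth-level) -------------
    base_cases: list[CaseRecord] = []
    case_counter = 0
    for j in range(config.n_youth):
        youth_id = f"youth-{j:05d}"
        n_arrests = 1 + int(rng.poisson(config.arrests_per_youth_mean - 1.0))
        cms = _choice(rng, cms_labels, cms_probs)
        county = f"{cms}-C{int(rng.integers(1, 4))}"
        gender = _choice(rng, sorted(margins["gender"]),
                         [margins["gender"][g] for g in sorted(margins["gender"])])
        race_keys = sorted(margins["race_ethnicity"])
        race = _choice(rng, race_keys, [margins["race_ethnicity"][r] for r in race_keys])
        age_keys = sorted(margins["age"])
        age = _choice(rng, age_keys, [margins["age"][a] for a in age_keys])
        truth.youth_case_counts[youth_id] = n_arrests
        for _ in range(n_arrests):
            charge_keys = sorted(margins["charge_severity"])
            charge = _choice(
                rng, charge_keys, [margins["charge_severity"][c] for c in charge_keys]
            )
            kind = _choice(rng, traj_kinds, traj_probs)
            detained = bool(rng.random() < config.detention_prob)
            points = sample_trajectory(kind, detained, rng)
            base_cases.append(
                CaseRecord(
                    case_id=f"case-{case_counter:06d}",
                    youth_id=youth_id,
                    cms_id=cms,
                    county_id=county,
                    extraction_phase=Phase.PRE,
                    gender=gender,
                    race_ethnicity=race,
                    age_years=int(age),
                    charge_severity=charge,
                    points=points,
                )
            )
            case_counter += 1
    n_cases = len(base_cases)

    # --- layer 1: missingness mask (drawn once, never altered) -------------
    masks: list[frozenset[DecisionPoint]] = []
    for _ in range(n_cases):
        mask = frozenset(
            p for p in DecisionPoint if rng.random() < config.missingness_rates[p]
        )
        masks.append(mask)

    # --- layer 2: disjoint rule injection, mask-compatible cases only ------
    rules = sorted(config.injection_rates, key=lambda r: r.name)
    quotas = {r: int(round(config.injection_rates[r] * n_cases)) for r in rules}
    order = list(rng.permutation(n_cases))
    assignment: dict[int, tuple[RuleId, Strategy]] = {}
    cursor = 0
    for rule in rules:
        mix = config.scenario_mix.get(rule, {})
        scenarios = sorted((s for s in mix if mix[s] > 0), key=lambda s: s.name)
        filled = 0
        while filled < quotas[rule] and cursor < len(order):
            idx = order[cursor]
            cursor += 1
            compatible = [s for s in scenarios if scenario_compatible(rule, s, masks[idx])]
            if not compatible:
                continue  # case stays uncorrupted; try the next one
            scenario = _choice(rng, compatible, [mix[s] for s in compatible])
            assignment[int(idx)] = (rule, scenario)
            filled += 1

    # --- assemble records: trajectory + mask (+ corruption) ----------------
    final: list[CaseRecord] = []
    pinned: list[frozenset[DecisionPoint]] = []
    for idx, rec in enumerate(base_cases):
        mask = masks[idx]
        truth_entry = CaseTruth(injected_missing=mask)
        if idx in assignment:
            rule, scenario = assignment[idx]
            original, corrupted = inject(rec, rule, scenario, rng, mask=mask)
            out = corrupted
            truth_entry.injected_rule = rule
            truth_entry.injected_scenario = scenario
            truth_entry.original = original
            pinned.append(pattern_points(rule, corrupted))
        else:
            out = replace(
                rec, points={p: (MISSING if p in mask else rec.points[p]) for p in DecisionPoint}
            )
            pinned.append(frozenset())
        final.append(out)
        truth.per_case[out.case_id] = truth_entry

    # --- layer 3: conformance noise in raw-token space ---------------------
    rows = []
    for idx, rec in enumerate(final):
        tokens: dict[DecisionPoint, str] = {}
        if config.conformance_noise_rate > 0:
            for p in DecisionPoint:
                if p in pinned[idx]:
                    continue
                if rng.random() < config.conformance_noise_rate:
                    tokens[p] = str(rng.choice(NONCONFORMING_TOKENS))
            if tokens:
                truth.per_case[rec.case_id].injected_nonconforming = frozenset(
                    (p.column, tok) for p, tok in tokens.items()
                )
        rows.append(_raw_row(rec, tokens))

    # bookkeeping tallies for the demographics report
    for rec in final:
        cms_tally = truth.demographic_counts.setdefault(rec.cms_id, {})
        for dim, value in [
            ("gender", rec.gender),
            ("race_ethnicity", rec.race_ethnicity),
            ("age", rec.age_years),
            ("charge_severity", rec.charge_severity),
        ]:
            d = cms_tally.setdefault(dim, {})
            d[value] = d.get(value, 0) + 1

    extract = parse_rows(rows, provenance=f"synthetic(seed={config.seed})")
    return extract, truth
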