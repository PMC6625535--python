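"""Resolution of flagged cases: field corrections, exclusions, action log.

Each plausibility rule has a small menu of resolution strategies mirroring
how such errors arise in practice:

* inconsistent petition — the diversion was OVERTURNED by the prosecutor
  (diverted→no, petitioned stays yes), or the youth VIOLATED_AGREEMENT of an
  informal adjustment (diverted stays yes, petitioned→no);
* implausible case — a COURTESY_DETENTION held for another county's court
  (the case is excluded from this county's totals), or a CLERICAL error
  requiring full-chronology review (left in place, still flagged);
* excess information — UNLINK values belonging to a different arrest
  (offending subsequent yes values→missing), or FIX_DIVERSION when the
  diversion field itself was wrong (diverted→no);
* inconsistent waiver — FIX: the post-waiver activity is a data-entry error
  (offending subsequent yes values→no);
* inconsistent adjudication — BACKFILL: the subsequent dispositions reflect
  the true outcome, so adjudicated→yes.

Because real resolutions came from paper court files, which no pipeline can
consult, the choice of scenario per case is supplied by a declarative
:class:`ResolutionPolicy` (per-rule defaults plus per-case overrides — for
synthetic data, the generator's injected ground-truth scenario).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import yaml

from .errors import PolicyError
from .records import CaseRecord, DecisionPoint, Extract, Phase, ResponseValue
from .rules import (
    SUBSEQUENT_TO_DIVERSION,
    SUBSEQUENT_TO_WAIVER,
    AuditResult,
    InconsistencyFlag,
    RuleId,
)

__all__ = [
    "Strategy",
    "STRATEGY_MENU",
    "DEFAULT_STRATEGIES",
    "CleaningAction",
    "ResolutionPolicy",
    "CleanResult",
    "EXCLUDED",
    "resolve_case",
    "clean_extract",
    "write_action_log",
]

YES = ResponseValue.YES
NO = ResponseValue.NO
MISSING = ResponseValue.MISSING
D = DecisionPoint


class Strategy(Enum):
    """Resolution scenarios, grouped per rule by :data:`STRATEGY_MENU`."""

    OVERTURNED = "overturned"
    VIOLATED_AGREEMENT = "violated_agreement"
    COURTESY_DETENTION = "courtesy_detention"
    CLERICAL = "clerical"
    UNLINK = "unlink"
    FIX_DIVERSION = "fix_diversion"
    FIX = "fix"
    BACKFILL = "backfill"

    def __repr__(self) -> str:
        return self.name


STRATEGY_MENU: dict[RuleId, tuple[Strategy, ...]] = {
    RuleId.INCONSISTENT_PETITION: (Strategy.OVERTURNED, Strategy.VIOLATED_AGREEMENT),
    RuleId.IMPLAUSIBLE_CASE: (Strategy.COURTESY_DETENTION, Strategy.CLERICAL),
    RuleId.EXCESS_INFORMATION: (Strategy.UNLINK, Strategy.FIX_DIVERSION),
    RuleId.INCONSISTENT_WAIVER: (Strategy.FIX,),
    RuleId.INCONSISTENT_ADJUDICATION: (Strategy.BACKFILL,),
}

#: Per-rule default when a policy names no strategy for a case.
DEFAULT_STRATEGIES: dict[RuleId, Strategy] = {
    RuleId.INCONSISTENT_PETITION: Strategy.OVERTURNED,
    RuleId.IMPLAUSIBLE_CASE: Strategy.COURTESY_DETENTION,
    RuleId.EXCESS_INFORMATION: Strategy.UNLINK,
    RuleId.INCONSISTENT_WAIVER: Strategy.FIX,
    RuleId.INCONSISTENT_ADJUDICATION: Strategy.BACKFILL,
}

#: Sentinel returned by resolve_case for county-denominator exclusions.
EXCLUDED = object()


@dataclass(frozen=True)
class CleaningAction:
    """The resolution applied to one flagged case."""

    case_id: str
    rule: RuleId
    strategy: Strategy
    field_edits: tuple[tuple[DecisionPoint, ResponseValue, ResponseValue], ...]
    excluded_from_county: bool
    resolved: bool

    def __post_init__(self) -> None:
        if self.excluded_from_county and self.field_edits:
            raise ValueError("an excluded case carries no field edits")


@dataclass
class ResolutionPolicy:
    """Declarative stand-in for case-by-case file review.

    ``per_rule`` sets a default strategy per rule; ``overrides`` pins a
    strategy to a specific case_id (for synthetic extracts, typically the
    generator's injected ground-truth scenario).
    """

    per_rule: dict[RuleId, Strategy] = field(default_factory=lambda: dict(DEFAULT_STRATEGIES))
    overrides: dict[str, Strategy] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for rule, strategy in self.per_rule.items():
            if strategy not in STRATEGY_MENU[rule]:
                raise PolicyError(f"strategy {strategy.name} not in menu of rule {rule.name}")

    def strategy_for(self, case_id: str, rule: RuleId) -> Strategy:
        strategy = self.overrides.get(case_id, self.per_rule.get(rule))
        if strategy is None:
            raise PolicyError(f"policy has no strategy for rule {rule.name}")
        if strategy not in STRATEGY_MENU[rule]:
            raise PolicyError(
                f"strategy {strategy.name} not in menu of rule {rule.name} (case {case_id})"
            )
        return strategy

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResolutionPolicy":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        per_rule = dict(DEFAULT_STRATEGIES)
        for rule_name, strat_name in (raw.get("per_rule") or {}).items():
            per_rule[RuleId[rule_name]] = Strategy[strat_name]
        overrides = {cid: Strategy[s] for cid, s in (raw.get("overrides") or {}).items()}
        return cls(per_rule=per_rule, overrides=overrides, seed=int(raw.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "per_rule": {r.name: s.name for r, s in self.per_rule.items()},
            "overrides": {cid: s.name for cid, s in self.overrides.items()},
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(payload, handle, sort_keys=True)


def _edit(
    case: CaseRecord, updates: dict[DecisionPoint, ResponseValue]
) -> tuple[CaseRecord, tuple[tuple[DecisionPoint, ResponseValue, ResponseValue], ...]]:
    """Apply point edits, recording (field, old, new) for actually-changed fields."""
    new_points = dict(case.points)
    edits = []
    for point, new_value in updates.items():
        old = new_points[point]
        if old is not new_value:
            edits.append((point, old, new_value))
            new_points[point] = new_value
    return replace(case, points=new_points), tuple(edits)


def resolve_case(
    case: CaseRecord, flag: InconsistencyFlag, policy: ResolutionPolicy
) -> tuple[CaseRecord | object, CleaningAction]:
    """Resolve one flagged case under the policy's strategy for it.

    Returns ``(edited_case, action)``, or ``(EXCLUDED, action)`` for a
    courtesy detention. The resolved rule never refires on the edited case;
    a CLERICAL action leaves the case untouched and marked unresolved.
    """
    strategy = policy.strategy_for(case.case_id, flag.rule)
    excluded = False
    resolved = True
    edits: tuple = ()
    out: CaseRecord | object = case

    if strategy is Strategy.OVERTURNED:
        out, edits = _edit(case, {D.DIVERTED: NO, D.PETITIONED: YES})
    elif strategy is Strategy.VIOLATED_AGREEMENT:
        out, edits = _edit(case, {D.DIVERTED: YES, D.PETITIONED: NO})
    elif strategy is Strategy.COURTESY_DETENTION:
        out, excluded = EXCLUDED, True
    elif strategy is Strategy.CLERICAL:
        resolved = False
    elif strategy is Strategy.UNLINK:
        offenders = [q for q in SUBSEQUENT_TO_DIVERSION if case.points[q] is YES]
        out, edits = _edit(case, {q: MISSING for q in offenders})
    elif strategy is Strategy.FIX_DIVERSION:
        out, edits = _edit(case, {D.DIVERTED: NO})
    elif strategy is Strategy.FIX:
        offenders = [q for q in SUBSEQUENT_TO_WAIVER if case.points[q] is YES]
        out, edits = _edit(case, {q: NO for q in offenders})
    elif strategy is Strategy.BACKFILL:
        out, edits = _edit(case, {D.ADJUDICATED: YES})

    action = CleaningAction(
        case_id=case.case_id,
        rule=flag.rule,
        strategy=strategy,
        field_edits=edits,
        excluded_from_county=excluded,
        resolved=resolved,
    )
    return out, action


@dataclass
class CleanResult:
    """Output of one cleaning pass over an extract."""

    post: Extract
    excluded: list[CaseRecord]
    actions: list[CleaningAction]  # flagged, non-CLERICAL cases only
    unresolved: list[str]  # case_ids left flagged for full-chronology review


def clean_extract(
    extract: Extract, audit_result: AuditResult, policy: ResolutionPolicy
) -> CleanResult:
    """Apply the policy's resolutions to every flagged case.

    Conservation holds exactly: post records + excluded records = input
    records, as case_id sets. Unflagged cases pass through untouched (phase
    relabelled POST). Cleaning is idempotent under a fixed policy: resolved
    patterns do not refire, and CLERICAL cases persist flagged but unchanged.
    """
    post_records: list[CaseRecord] = []
    excluded: list[CaseRecord] = []
    actions: list[CleaningAction] = []
    unresolved: list[str] = []
    for rec in extract.records:
        flag = audit_result.first_error.get(rec.case_id)
        if flag is None:
            post_records.append(replace(rec, extraction_phase=Phase.POST))
            continue
        out, action = resolve_case(rec, flag, policy)
        if out is EXCLUDED:
            excluded.append(rec)
            actions.append(action)
        else:
            post_records.append(replace(out, extraction_phase=Phase.POST))
            if action.strategy is Strategy.CLERICAL:
                unresolved.append(rec.case_id)
            else:
                actions.append(action)
    post = Extract(records=post_records, provenance=f"{extract.provenance}→post-cleaning")
    return CleanResult(post=post, excluded=excluded, actions=actions, unresolved=unresolved)


def write_action_log(actions: list[CleaningAction], path: str | Path | io.TextIOBase) -> None:
    """Action log as CSV: one row per field edit (or per exclusion)."""

    def _write(handle: io.TextIOBase) -> None:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["case_id", "rule", "strategy", "field", "old", "new", "excluded"])
        for a in actions:
            if a.field_edits:
                for point, old, new in a.field_edits:
                    writer.writerow(
                        [a.case_id, a.rule.value, a.strategy.value, point.column, old.value,
                         new.value, str(a.excluded_from_county).lower()]
                    )
            else:
                writer.writerow(
                    [a.case_id, a.rule.value, a.strategy.value, "", "", "",
                     str(a.excluded_from_county).lower()]
                )

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as handle:
            _write(handle)
    else:
        _write(path)
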