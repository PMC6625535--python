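"""Conformance, completeness and plausibility auditing of case extracts.

Three dimensions of data quality are measured on each extract:

* **conformance** — raw decision-point tokens outside the yes/no/missing
  vocabulary (captured at parse time, tallied here);
* **completeness** — percent of cases missing each decision point;
* **plausibility** — five within-case logical-inconsistency rules over the
  seven decision points, with *first-inconsistency* accounting: although a
  case may violate several rules, only the rule whose pattern occurs
  earliest in case chronology is recorded, so the per-rule categories
  partition the flagged cases.

MISSING matches neither a YES nor a NO literal in any rule, and DETAINED —
which may occur at any time — participates in no rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .errors import EmptyExtractError
from .records import CaseRecord, DecisionPoint, Extract, ResponseValue

__all__ = [
    "RuleId",
    "InconsistencyFlag",
    "AuditResult",
    "ConformanceReport",
    "RULE_PRIORITY",
    "percent",
    "check_conformance",
    "completeness_profile",
    "detect_all",
    "first_inconsistency",
    "audit",
]

YES = ResponseValue.YES
NO = ResponseValue.NO
D = DecisionPoint


class RuleId(Enum):
    """The five plausibility rules (within-case logical inconsistencies)."""

    INCONSISTENT_PETITION = "inconsistent_petition"
    IMPLAUSIBLE_CASE = "implausible_case"
    EXCESS_INFORMATION = "excess_information"
    INCONSISTENT_WAIVER = "inconsistent_waiver"
    INCONSISTENT_ADJUDICATION = "inconsistent_adjudication"

    def __repr__(self) -> str:
        return self.name


#: Decision points chronologically subsequent to a diversion (order-exempt
#: DETAINED excluded). A diverted case should show nothing further.
SUBSEQUENT_TO_DIVERSION = (D.ADJUDICATED, D.PROBATION, D.CONFINED, D.WAIVED)
#: Points that imply continued juvenile-court activity after a waiver.
SUBSEQUENT_TO_WAIVER = (D.ADJUDICATED, D.PROBATION, D.CONFINED)
#: Dispositions that presuppose a delinquency adjudication.
LATER_THAN_ADJUDICATION = (D.PROBATION, D.CONFINED)

#: Fixed tie-break order when two rules share a chronological anchor.
RULE_PRIORITY = (
    RuleId.INCONSISTENT_PETITION,
    RuleId.IMPLAUSIBLE_CASE,
    RuleId.EXCESS_INFORMATION,
    RuleId.INCONSISTENT_ADJUDICATION,
    RuleId.INCONSISTENT_WAIVER,
)
_PRIORITY_INDEX = {rule: i for i, rule in enumerate(RULE_PRIORITY)}


@dataclass(frozen=True)
class InconsistencyFlag:
    """One fired plausibility rule on a case.

    ``anchor_position`` is the canonical position of the decision point at
    which the pattern first becomes detectable in case chronology; it drives
    the first-inconsistency accounting.
    """

    rule: RuleId
    anchor_position: int
    involved_points: frozenset[DecisionPoint]


def detect_all(case: CaseRecord, adjudication_missing_counts: bool = False) -> set[InconsistencyFlag]:
    """Evaluate all five plausibility rules on one case.

    With ``adjudication_missing_counts`` the inconsistent-adjudication rule
    also fires when the adjudication field is blank (the common real-world
    origin of that error); by default only an explicit NO triggers it.
    """
    p = case.points
    flags: set[InconsistencyFlag] = set()

    if p[D.DIVERTED] is YES and p[D.PETITIONED] is YES:
        flags.add(
            InconsistencyFlag(
                RuleId.INCONSISTENT_PETITION,
                anchor_position=D.PETITIONED.canonical_position,
                involved_points=frozenset({D.DIVERTED, D.PETITIONED}),
            )
        )

    if p[D.DIVERTED] is NO and p[D.PETITIONED] is NO:
        flags.add(
            InconsistencyFlag(
                RuleId.IMPLAUSIBLE_CASE,
                anchor_position=D.PETITIONED.canonical_position,
                involved_points=frozenset({D.DIVERTED, D.PETITIONED}),
            )
        )

    if p[D.DIVERTED] is YES:
        offending = [q for q in SUBSEQUENT_TO_DIVERSION if p[q] is YES]
        if offending:
            flags.add(
                InconsistencyFlag(
                    RuleId.EXCESS_INFORMATION,
                    anchor_position=min(q.canonical_position for q in offending),
                    involved_points=frozenset({D.DIVERTED, *offending}),
                )
            )

    if p[D.WAIVED] is YES:
        offending = [q for q in SUBSEQUENT_TO_WAIVER if p[q] is YES]
        if offending:
            flags.add(
                InconsistencyFlag(
                    RuleId.INCONSISTENT_WAIVER,
                    anchor_position=D.WAIVED.canonical_position,
                    involved_points=frozenset({D.WAIVED, *offending}),
                )
            )

    adjudication_denies = p[D.ADJUDICATED] is NO or (
        adjudication_missing_counts and p[D.ADJUDICATED] is ResponseValue.MISSING
    )
    if adjudication_denies:
        offending = [q for q in LATER_THAN_ADJUDICATION if p[q] is YES]
        if offending:
            flags.add(
                InconsistencyFlag(
                    RuleId.INCONSISTENT_ADJUDICATION,
                    anchor_position=min(q.canonical_position for q in offending),
                    involved_points=frozenset({D.ADJUDICATED, *offending}),
                )
            )

    return flags


def first_inconsistency(
    case: CaseRecord, adjudication_missing_counts: bool = False
) -> InconsistencyFlag | None:
    """The single inconsistency recorded for a case: earliest anchor wins.

    A case with both an inconsistent petition (anchor 3, petitioned) and an
    inconsistent waiver (anchor 7) is recorded as an inconsistent petition
    only. Ties at equal anchors break by the fixed :data:`RULE_PRIORITY`.
    """
    flags = detect_all(case, adjudication_missing_counts=adjudication_missing_counts)
    if not flags:
        return None
    return min(flags, key=lambda f: (f.anchor_position, _PRIORITY_INDEX[f.rule]))


def percent(count: int, total: int) -> float:
    """Percentage to one decimal, rounded half-up (report-table convention)."""
    if total <= 0:
        raise EmptyExtractError("percentage undefined for an empty denominator")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class ConformanceReport:
    """Nonconforming-token tally, itemized by decision-point field."""

    count: int
    by_field: dict[DecisionPoint, list]


def check_conformance(extract: Extract) -> ConformanceReport:
    """Tally the raw-token violations captured when the extract was parsed."""
    by_field: dict[DecisionPoint, list] = {p: [] for p in DecisionPoint}
    for v in extract.conformance_violations:
        by_field[v.field].append(v)
    by_field = {p: vs for p, vs in by_field.items() if vs}
    return ConformanceReport(count=len(extract.conformance_violations), by_field=by_field)


def completeness_profile(extract: Extract) -> dict[DecisionPoint, float]:
    """Percent of cases with MISSING at each decision point, to one decimal."""
    if extract.n_cases == 0:
        raise EmptyExtractError("completeness undefined on an empty extract")
    n = extract.n_cases
    return {
        p: percent(sum(1 for rec in extract.records if rec.points[p] is ResponseValue.MISSING), n)
        for p in DecisionPoint
    }


@dataclass
class AuditResult:
    """Quality audit of one extract: first-error assignments plus tallies.

    ``per_rule_counts`` counts cases whose *first* error is each rule, so the
    counts partition the flagged cases and sum to ``at_least_one_count``.
    """

    n_cases: int
    first_error: dict[str, InconsistencyFlag | None]
    completeness: dict[DecisionPoint, float]
    per_rule_counts: dict[RuleId, int]
    conformance_count: int

    @property
    def at_least_one_count(self) -> int:
        return sum(1 for f in self.first_error.values() if f is not None)

    @property
    def at_least_one_pct(self) -> float:
        return percent(self.at_least_one_count, self.n_cases)

    def per_rule_pct(self, rule: RuleId) -> float:
        return percent(self.per_rule_counts[rule], self.n_cases)

    def to_dict(self) -> dict:
        """JSON-ready audit summary."""
        return {
            "n_cases": self.n_cases,
            "completeness": {p.column: v for p, v in self.completeness.items()},
            "per_rule": {
                r.value: {"count": self.per_rule_counts[r], "pct": self.per_rule_pct(r)}
                for r in RuleId
            },
            "at_least_one": {"count": self.at_least_one_count, "pct": self.at_least_one_pct},
            "conformance": self.conformance_count,
        }


def audit(extract: Extract, adjudication_missing_counts: bool = False) -> AuditResult:
    """Full quality audit: completeness, first-error plausibility, conformance."""
    if extract.n_cases == 0:
        raise EmptyExtractError("cannot audit an empty extract")
    first_error: dict[str, InconsistencyFlag | None] = {}
    per_rule_counts: dict[RuleId, int] = {r: 0 for r in RuleId}
    for rec in extract.records:
        flag = first_inconsistency(rec, adjudication_missing_counts=adjudication_missing_counts)
        first_error[rec.case_id] = flag
        if flag is not None:
            per_rule_counts[flag.rule] += 1
    return AuditResult(
        n_cases=extract.n_cases,
        first_error=first_error,
        completeness=completeness_profile(extract),
        per_rule_counts=per_rule_counts,
        conformance_count=len(extract.conformance_violations),
    )
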