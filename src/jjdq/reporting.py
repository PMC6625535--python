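"""Report tables: demographics, completeness pre/post, plausibility pre/post.

Three tables summarise an audited extract the way county data-quality
reviews print them:

* a per-CMS case-description table (gender, race/ethnicity, age with mean
  and SD, charge severity) with *small-cell suppression*: any count strictly
  between 0 and the threshold (default 10) displays a sentinel like ``<10``
  to limit re-identification — zeros are shown;
* a completeness table, percent missing per decision point, side-by-side
  pre-/post-cleaning columns per CMS;
* a plausibility table, percent of cases per first-recorded inconsistency
  plus an "at least one inconsistency" row (the exact column sum of the rule
  rows before rounding, since first-error categories partition the cases).

A CMS that supplied no post-cleaning extract gets blank post columns; a CMS
that supplied no values for a demographic dimension gets blank cells there.
Percent denominators are always *all cases in the CMS*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import StructuralError
from .records import (
    CHARGE_SEVERITIES,
    CaseRecord,
    DecisionPoint,
    Extract,
    GENDERS,
    RACE_ETHNICITIES,
    AGE_MIN,
    AGE_MAX,
)
from .rules import AuditResult, RuleId, audit, percent

__all__ = [
    "POINT_LABELS",
    "RULE_LABELS",
    "QualityReport",
    "demographics_table",
    "demographics_counts",
    "comparison_tables",
    "build_report",
    "render",
]

POINT_LABELS = {
    DecisionPoint.DIVERTED: "Diverted",
    DecisionPoint.DETAINED: "Detained",
    DecisionPoint.PETITIONED: "Petitioned",
    DecisionPoint.ADJUDICATED: "Adjudicated delinquent",
    DecisionPoint.PROBATION: "Placed on probation",
    DecisionPoint.CONFINED: "Confined",
    DecisionPoint.WAIVED: "Waived",
}

RULE_LABELS = {
    RuleId.INCONSISTENT_PETITION: "Inconsistent petition",
    RuleId.IMPLAUSIBLE_CASE: "Implausible case",
    RuleId.EXCESS_INFORMATION: "Excess information",
    RuleId.INCONSISTENT_WAIVER: "Inconsistent waiver",
    RuleId.INCONSISTENT_ADJUDICATION: "Inconsistent adjudication",
}

AT_LEAST_ONE_LABEL = "At least one inconsistency"

_DIMENSIONS = ("gender", "race_ethnicity", "age", "charge_severity")
_CATEGORIES: dict[str, list] = {
    "gender": list(GENDERS),
    "race_ethnicity": list(RACE_ETHNICITIES),
    "age": list(range(AGE_MIN, AGE_MAX + 1)),
    "charge_severity": list(CHARGE_SEVERITIES),
}


def _value_of(rec: CaseRecord, dimension: str):
    return {
        "gender": rec.gender,
        "race_ethnicity": rec.race_ethnicity,
        "age": rec.age_years,
        "charge_severity": rec.charge_severity,
    }[dimension]


def demographics_counts(extract: Extract) -> dict[str, dict[str, dict]]:
    """Raw (unsuppressed) per-CMS counts by dimension and category."""
    counts: dict[str, dict[str, dict]] = {}
    for cms, sub in extract.by_cms().items():
        per_dim: dict[str, dict] = {}
        for dim in _DIMENSIONS:
            tally: dict = {c: 0 for c in _CATEGORIES[dim]}
            tally["missing"] = 0
            for rec in sub.records:
                value = _value_of(rec, dim)
                tally["missing" if value is None else value] += 1
            per_dim[dim] = tally
        counts[cms] = per_dim
    return counts


def demographics_table(extract: Extract, suppression_threshold: int = 10) -> pd.DataFrame:
    """Per-CMS case-description table with small-cell suppression.

    Cells with ``0 < count < suppression_threshold`` display the sentinel
    ``<T`` and a blank percent; zero counts display as 0. A CMS whose cases
    carry no values at all for a dimension renders that dimension's cells
    blank. Percents use all cases in the CMS as denominator; the age block
    additionally carries a ``Mean age (SD)`` row.
    """
    counts = demographics_counts(extract)
    cms_list = sorted(counts)
    sentinel = f"<{suppression_threshold}"

    rows: list[dict[str, str]] = []

    def make_row(dimension: str, category: str) -> dict[str, str]:
        return {"dimension": dimension, "category": category}

    by_cms = extract.by_cms()
    for dim in _DIMENSIONS:
        for category in _CATEGORIES[dim] + ["missing"]:
            row = make_row(dim, str(category))
            for cms in cms_list:
                n_cms = by_cms[cms].n_cases
                dim_counts = counts[cms][dim]
                supplied = any(
                    _value_of(rec, dim) is not None for rec in by_cms[cms].records
                )
                c = dim_counts[category]
                if not supplied:
                    row[f"{cms} n"] = ""
                    row[f"{cms} %"] = ""
                elif 0 < c < suppression_threshold:
                    row[f"{cms} n"] = sentinel
                    row[f"{cms} %"] = ""
                else:
                    row[f"{cms} n"] = str(c)
                    row[f"{cms} %"] = f"{percent(c, n_cms):.1f}"
            rows.append(row)
        if dim == "age":
            row = make_row(dim, "Mean age (SD)")
            for cms in cms_list:
                ages = [rec.age_years for rec in by_cms[cms].records if rec.age_years is not None]
                if ages:
                    mean = sum(ages) / len(ages)
                    var = sum((a - mean) ** 2 for a in ages) / (len(ages) - 1) if len(ages) > 1 else 0.0
                    row[f"{cms} n"] = f"{mean:.1f} ({math.sqrt(var):.1f})"
                else:
                    row[f"{cms} n"] = ""
                row[f"{cms} %"] = ""
            rows.append(row)

    columns = ["dimension", "category"]
    for cms in cms_list:
        columns += [f"{cms} n", f"{cms} %"]
    return pd.DataFrame(rows, columns=columns)


def _blank_column(labels: list[str]) -> list[str]:
    return ["" for _ in labels]


def comparison_tables(
    pre_audit: Mapping[str, AuditResult],
    post_audit: Mapping[str, AuditResult] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side pre/post completeness and plausibility tables.

    ``post_audit`` may be None (all post columns blank) or cover only a
    subset of the pre CMS set (blank columns for the absent ones — the
    pattern of a system that never supplied a second extract). A post CMS
    absent from pre is a structural error.
    """
    post_audit = post_audit or {}
    stray = sorted(set(post_audit) - set(pre_audit))
    if stray:
        raise StructuralError(f"post audit covers CMS absent from pre: {stray}")

    cms_list = sorted(pre_audit)

    point_labels = [POINT_LABELS[p] for p in DecisionPoint]
    completeness = pd.DataFrame({"decision_point": point_labels})
    for cms in cms_list:
        completeness[f"{cms} pre"] = [
            f"{pre_audit[cms].completeness[p]:.1f}" for p in DecisionPoint
        ]
        if cms in post_audit:
            completeness[f"{cms} post"] = [
                f"{post_audit[cms].completeness[p]:.1f}" for p in DecisionPoint
            ]
        else:
            completeness[f"{cms} post"] = _blank_column(point_labels)

    rule_labels = [RULE_LABELS[r] for r in RuleId] + [AT_LEAST_ONE_LABEL]
    plausibility = pd.DataFrame({"inconsistency": rule_labels})
    for cms in cms_list:
        def col(a: AuditResult) -> list[str]:
            return [f"{a.per_rule_pct(r):.1f}" for r in RuleId] + [f"{a.at_least_one_pct:.1f}"]

        plausibility[f"{cms} pre"] = col(pre_audit[cms])
        plausibility[f"{cms} post"] = (
            col(post_audit[cms]) if cms in post_audit else _blank_column(rule_labels)
        )
    return completeness, plausibility


@dataclass
class QualityReport:
    """The three rendered tables plus the suppression threshold used."""

    demographics: pd.DataFrame
    completeness: pd.DataFrame
    plausibility: pd.DataFrame
    suppression_threshold: int = 10

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QualityReport):
            return NotImplemented
        return (
            self.suppression_threshold == other.suppression_threshold
            and self.demographics.equals(other.demographics)
            and self.completeness.equals(other.completeness)
            and self.plausibility.equals(other.plausibility)
        )

    def to_json(self) -> str:
        def pack(df: pd.DataFrame) -> dict:
            return {"columns": list(df.columns), "data": df.values.tolist()}

        return json.dumps(
            {
                "suppression_threshold": self.suppression_threshold,
                "demographics": pack(self.demographics),
                "completeness": pack(self.completeness),
                "plausibility": pack(self.plausibility),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "QualityReport":
        raw = json.loads(payload)

        def unpack(blob: dict) -> pd.DataFrame:
            return pd.DataFrame(blob["data"], columns=blob["columns"], dtype=object)

        return cls(
            demographics=unpack(raw["demographics"]),
            completeness=unpack(raw["completeness"]),
            plausibility=unpack(raw["plausibility"]),
            suppression_threshold=raw["suppression_threshold"],
        )


def build_report(
    pre_extract: Extract,
    post_extract: Extract | None = None,
    suppression_threshold: int = 10,
    adjudication_missing_counts: bool = False,
) -> QualityReport:
    """Audit per CMS and assemble the three report tables."""
    pre_audits = {
        cms: audit(sub, adjudication_missing_counts=adjudication_missing_counts)
        for cms, sub in pre_extract.by_cms().items()
    }
    post_audits = None
    if post_extract is not None and post_extract.n_cases:
        post_audits = {
            cms: audit(sub, adjudication_missing_counts=adjudication_missing_counts)
            for cms, sub in post_extract.by_cms().items()
        }
    completeness, plausibility = comparison_tables(pre_audits, post_audits)
    return QualityReport(
        demographics=demographics_table(pre_extract, suppression_threshold),
        completeness=completeness,
        plausibility=plausibility,
        suppression_threshold=suppression_threshold,
    )


_CSV_NAMES = {
    "demographics": "report_demographics.csv",
    "completeness": "report_completeness.csv",
    "plausibility": "report_plausibility.csv",
}


def render(report: QualityReport, format: str, outdir: str | Path | None = None) -> dict[str, str]:
    """Serialize a report; returns {filename: content}, writing if outdir given.

    ``json`` round-trips to an equal report via :meth:`QualityReport.from_json`;
    ``csv`` emits the three tables; ``text`` a human-readable rendering.
    Output is deterministic for a fixed report.
    """
    if format == "json":
        outputs = {"report.json": report.to_json()}
    elif format == "csv":
        outputs = {
            _CSV_NAMES[name]: getattr(report, name).to_csv(index=False, lineterminator="\n")
            for name in _CSV_NAMES
        }
    elif format == "text":
        parts = []
        for title, df in [
            ("Case description by CMS", report.demographics),
            ("Completeness: % cases missing per decision point (pre/post)", report.completeness),
            ("Plausibility: % cases per first logical inconsistency (pre/post)", report.plausibility),
        ]:
            body = df.to_string(index=False) if len(df) else "(empty)"
            parts.append(f"== {title} ==\n{body}\n")
        outputs = {"report.txt": "\n".join(parts)}
    else:
        raise ValueError(f"unknown render format {format!r} (expected csv, json or text)")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, content in outputs.items():
            (outdir / name).write_text(content, encoding="utf-8")
    return outputs
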