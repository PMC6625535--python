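"""Domain model for juvenile-justice case extracts and bit-exact CSV I/O.

One row of an extract is one *case* (one arrest of one youth). Each case
carries seven decision-point fields — diverted, detained, petitioned,
adjudicated delinquent, placed on probation, confined, waived — each valued
yes / no / missing. A youth may contribute several cases; the youth-level
view is derived by :func:`cases_by_youth`, never stored.

Raw tokens outside the ``{"yes", "no", ""}`` vocabulary for a decision point
are *conformance violations*: they are recorded verbatim (for the conformance
report) and the field is set to MISSING so completeness and plausibility
checks still run. The empty string is the canonical missing token.
"""

from __future__ import annotations

import csv
import io
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import SchemaError, UniquenessError

__all__ = [
    "ResponseValue",
    "DecisionPoint",
    "Phase",
    "CaseRecord",
    "ConformanceViolation",
    "Extract",
    "CsvDialectConfig",
    "COLUMNS",
    "GENDERS",
    "RACE_ETHNICITIES",
    "CHARGE_SEVERITIES",
    "CMS_IDS",
    "read_extract",
    "write_extract",
    "cases_by_youth",
]


class ResponseValue(Enum):
    """Tri-state value of one decision point: yes, no or missing."""

    YES = "yes"
    NO = "no"
    MISSING = ""

    def __repr__(self) -> str:  # terse reprs keep test diffs readable
        return self.name


class Phase(Enum):
    """Extraction phase: before (PRE) or after (POST) site-led data cleaning."""

    PRE = "pre"
    POST = "post"


class DecisionPoint(Enum):
    """The seven juvenile-justice decision points, in case chronology.

    ``canonical_position`` is the 1-based chronological rank used by the
    first-inconsistency accounting. Detention is *order-exempt*: a youth can
    be detained before or after any other point, so DETAINED participates in
    no plausibility rule.
    """

    DIVERTED = ("diverted", 1)
    DETAINED = ("detained", 2)
    PETITIONED = ("petitioned", 3)
    ADJUDICATED = ("adjudicated", 4)
    PROBATION = ("probation", 5)
    CONFINED = ("confined", 6)
    WAIVED = ("waived", 7)

    def __init__(self, column: str, position: int) -> None:
        self.column = column
        self.canonical_position = position

    @property
    def order_exempt(self) -> bool:
        return self is DecisionPoint.DETAINED

    def __repr__(self) -> str:
        return self.name


#: Fixed extract column order (unknown extra columns are carried through).
COLUMNS = [
    "case_id",
    "youth_id",
    "cms_id",
    "county_id",
    "extraction_phase",
    "gender",
    "race_ethnicity",
    "age",
    "charge_severity",
    "diverted",
    "detained",
    "petitioned",
    "adjudicated",
    "probation",
    "confined",
    "waived",
]

CMS_IDS = ("CMS1", "CMS2", "CMS3", "CMS4")
GENDERS = ("male", "female")
RACE_ETHNICITIES = (
    "African American/Black",
    "Asian",
    "Hawaiian/Pacific Islander",
    "Hispanic/Latino",
    "Native American or Native Alaskan",
    "White",
    "Other",
)
CHARGE_SEVERITIES = (
    "Felony A",
    "Felony B",
    "Felony C",
    "Felony D",
    "Misdemeanor A",
    "Misdemeanor B",
    "Misdemeanor C",
    "Status Offense",
    "Violation of Probation",
)

_POINT_BY_COLUMN = {p.column: p for p in DecisionPoint}
_RACE_LOOKUP = {r.lower(): r for r in RACE_ETHNICITIES}
_CHARGE_LOOKUP = {c.lower(): c for c in CHARGE_SEVERITIES}

AGE_MIN, AGE_MAX = 10, 18


@dataclass(frozen=True)
class CsvDialectConfig:
    """CSV dialect for extract files (UTF-8, minimal quoting by default)."""

    delimiter: str = ","
    quotechar: str = '"'


@dataclass(frozen=True)
class ConformanceViolation:
    """One nonconforming raw token: where it sat and what it said."""

    row_index: int  # 0-based data-row index in the source file
    case_id: str
    field: DecisionPoint
    token: str


@dataclass
class CaseRecord:
    """One arrest ("case"): identifiers, demographics and the seven points.

    All seven decision points are always present as keys in ``points``;
    an absent value is ``ResponseValue.MISSING``, never an absent key.
    Demographic missingness is represented by ``None``.
    """

    case_id: str
    youth_id: str
    cms_id: str
    county_id: str
    extraction_phase: Phase
    gender: str | None
    race_ethnicity: str | None
    age_years: int | None
    charge_severity: str | None
    points: dict[DecisionPoint, ResponseValue]
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_keys = [p for p in DecisionPoint if p not in self.points]
        if missing_keys:
            raise ValueError(f"decision points absent from record: {missing_keys}")
        if self.age_years is not None and not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise ValueError(f"age_years {self.age_years} outside [{AGE_MIN}, {AGE_MAX}]")

    def with_points(self, **updates: ResponseValue) -> "CaseRecord":
        """Copy of this record with named decision-point columns replaced."""
        new_points = dict(self.points)
        for column, value in updates.items():
            new_points[_POINT_BY_COLUMN[column]] = value
        return replace(self, points=new_points)


@dataclass
class Extract:
    """An ordered collection of cases plus parse-time bookkeeping.

    ``records`` retain file order. Conformance violations captured during
    parsing are kept verbatim; rows that could not be parsed at all are
    counted in ``rejected_rows`` so that
    ``len(records) + len(rejected_rows)`` equals the source row count.
    """

    records: list[CaseRecord]
    provenance: str = ""
    conformance_violations: list[ConformanceViolation] = field(default_factory=list)
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.records)

    def by_cms(self) -> "OrderedDict[str, Extract]":
        """Split into per-CMS sub-extracts (violations follow their case)."""
        groups: OrderedDict[str, Extract] = OrderedDict()
        case_to_cms = {}
        for rec in self.records:
            grp = groups.setdefault(
                rec.cms_id, Extract(records=[], provenance=f"{self.provenance}[{rec.cms_id}]")
            )
            grp.records.append(rec)
            case_to_cms[(rec.case_id, rec.extraction_phase)] = rec.cms_id
        for v in self.conformance_violations:
            for phase in Phase:
                cms = case_to_cms.get((v.case_id, phase))
                if cms is not None:
                    groups[cms].conformance_violations.append(v)
                    break
        return groups


def _parse_point_token(raw: str) -> tuple[ResponseValue, bool]:
    """Map a raw decision-point token to its tri-state value.

    Returns ``(value, conforming)``; a nonconforming token maps to MISSING
    with ``conforming=False`` so the caller can record the violation.
    """
    token = raw.strip().lower()
    if token == "":
        return ResponseValue.MISSING, True
    if token == "yes":
        return ResponseValue.YES, True
    if token == "no":
        return ResponseValue.NO, True
    return ResponseValue.MISSING, False


def _parse_demographics(row: Mapping[str, str]) -> tuple[str | None, str | None, int | None, str | None]:
    gender_tok = row.get("gender", "").strip().lower()
    gender = gender_tok if gender_tok in GENDERS else None
    race = _RACE_LOOKUP.get(row.get("race_ethnicity", "").strip().lower())
    charge = _CHARGE_LOOKUP.get(row.get("charge_severity", "").strip().lower())
    age: int | None = None
    age_tok = row.get("age", "").strip()
    if age_tok:
        try:
            candidate = int(age_tok)
        except ValueError:
            candidate = None
        if candidate is not None and AGE_MIN <= candidate <= AGE_MAX:
            age = candidate
    return gender, race, age, charge


def parse_rows(
    rows: Iterable[Mapping[str, str]],
    provenance: str = "",
    extra_columns: Iterable[str] = (),
) -> Extract:
    """Build an :class:`Extract` from dict-shaped rows (the CSV reader's view).

    Shared by :func:`read_extract` and the synthetic generator so that both
    paths apply identical vocabulary rules.
    """
    extra_columns = list(extra_columns)
    extract = Extract(records=[], provenance=provenance)
    seen: set[tuple[str, Phase]] = set()
    for idx, row in enumerate(rows):
        if row is None:  # placeholder for a structurally malformed row
            continue
        case_id = (row.get("case_id") or "").strip()
        phase_tok = (row.get("extraction_phase") or "").strip().lower()
        try:
            phase = Phase(phase_tok)
        except ValueError:
            extract.rejected_rows.append((idx, f"bad extraction_phase {phase_tok!r}"))
            continue
        if not case_id:
            extract.rejected_rows.append((idx, "empty case_id"))
            continue
        key = (case_id, phase)
        if key in seen:
            raise UniquenessError(
                f"duplicate (case_id, extraction_phase) = ({case_id!r}, {phase.value!r}) at row {idx}"
            )
        seen.add(key)

        points: dict[DecisionPoint, ResponseValue] = {}
        for point in DecisionPoint:
            raw = row.get(point.column) or ""
            value, conforming = _parse_point_token(raw)
            points[point] = value
            if not conforming:
                extract.conformance_violations.append(
                    ConformanceViolation(row_index=idx, case_id=case_id, field=point, token=raw)
                )
        gender, race, age, charge = _parse_demographics(row)
        extract.records.append(
            CaseRecord(
                case_id=case_id,
                youth_id=(row.get("youth_id") or "").strip(),
                cms_id=(row.get("cms_id") or "").strip(),
                county_id=(row.get("county_id") or "").strip(),
                extraction_phase=phase,
                gender=gender,
                race_ethnicity=race,
                age_years=age,
                charge_severity=charge,
                points=points,
                extras={c: row.get(c, "") for c in extra_columns},
            )
        )
    return extract


def read_extract(path: str | Path | io.TextIOBase, dialect: CsvDialectConfig | None = None) -> Extract:
    """Read a case extract from CSV.

    The header must contain every documented column exactly once; unknown
    extra columns are carried through on each record. Raises
    :class:`SchemaError` for missing/duplicate header columns and
    :class:`UniquenessError` for a duplicate (case_id, phase) pair.
    """
    dialect = dialect or CsvDialectConfig()

    def _read(handle: io.TextIOBase, provenance: str) -> Extract:
        reader = csv.reader(handle, delimiter=dialect.delimiter, quotechar=dialect.quotechar)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("file has no header row") from None
        missing = [c for c in COLUMNS if c not in header]
        duplicated = sorted({c for c in header if header.count(c) > 1})
        if missing or duplicated:
            raise SchemaError(
                f"bad extract header: missing columns {missing}, duplicate columns {duplicated}"
            )
        extra = [c for c in header if c not in COLUMNS]
        dict_rows = []
        n_fields = len(header)
        malformed: list[tuple[int, str]] = []
        for idx, row in enumerate(reader):
            if len(row) != n_fields:
                malformed.append((idx, f"expected {n_fields} fields, got {len(row)}"))
                dict_rows.append(None)
                continue
            dict_rows.append(dict(zip(header, row)))
        extract = parse_rows(dict_rows, provenance=provenance, extra_columns=extra)
        if malformed:
            extract.rejected_rows.extend(malformed)
            extract.rejected_rows.sort()
        return extract

    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8", newline="") as handle:
            return _read(handle, provenance=str(path))
    return _read(path, provenance=getattr(path, "name", "<stream>"))


def _record_to_row(rec: CaseRecord, extra_columns: list[str]) -> list[str]:
    base = [
        rec.case_id,
        rec.youth_id,
        rec.cms_id,
        rec.county_id,
        rec.extraction_phase.value,
        rec.gender or "",
        rec.race_ethnicity or "",
        "" if rec.age_years is None else str(rec.age_years),
        rec.charge_severity or "",
    ]
    base.extend(rec.points[p].value for p in DecisionPoint)
    base.extend(rec.extras.get(c, "") for c in extra_columns)
    return base


def write_extract(
    extract: Extract, path: str | Path | io.TextIOBase, dialect: CsvDialectConfig | None = None
) -> None:
    """Write an extract as CSV; ``read_extract`` of the output round-trips."""
    dialect = dialect or CsvDialectConfig()
    extra_columns = sorted({c for rec in extract.records for c in rec.extras})

    def _write(handle: io.TextIOBase) -> None:
        writer = csv.writer(
            handle,
            delimiter=dialect.delimiter,
            quotechar=dialect.quotechar,
            quoting=csv.QUOTE_MINIMAL,
            lineterminator="\n",
        )
        writer.writerow(COLUMNS + extra_columns)
        for rec in extract.records:
            writer.writerow(_record_to_row(rec, extra_columns))

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as handle:
            _write(handle)
    else:
        _write(path)


def cases_by_youth(extract: Extract) -> "OrderedDict[str, list[CaseRecord]]":
    """Group cases by youth, preserving file order within each youth."""
    groups: OrderedDict[str, list[CaseRecord]] = OrderedDict()
    for rec in extract.records:
        groups.setdefault(rec.youth_id, []).append(rec)
    return groups
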