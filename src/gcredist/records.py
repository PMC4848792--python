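"""Individual death-certificate records: data model, I/O, categorization.

A certificate carries one underlying cause (the output of the registrar's
coding, e.g. ACME in the US) plus contributing causes placed on certificate
lines.  Lines 1-5 are Part I (the causal chain); line 6 stands for Part II,
"other significant conditions contributing to death but not resulting in
death".  Line-6 codes are excluded from all model covariates.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .causes import CauseList, DEFAULT_CAUSE_LIST, REVISION_ERAS, is_garbage
from .cause_map import CauseMap, map_code, normalize_icd

SEXES = ("male", "female")
PLACES = ("inpatient", "outpatient_er", "hospice", "nursing_ltc", "home", "other")

MICRODATA_HEADER = (
    "id", "year", "age", "sex", "state", "race", "place",
    "revision", "underlying", "contributing",
)


@dataclass(frozen=True)
class ContributingEntry:
    line: int        # certificate line 1-6 (6 = Part II)
    position: int    # >= 1, order within the line
    code: str        # normalized ICD code


@dataclass(frozen=True)
class DeathRecord:
    id: str
    year: int
    age: int
    sex: str
    state: str
    race: str
    place: str
    revision: int
    underlying: str
    contributing: tuple[ContributingEntry, ...] = ()


@dataclass(frozen=True)
class CategorizedRecord:
    """A record plus its condensed-cause view.

    ``part1_cats`` holds the distinct *valid* causes found on lines 1-5 (the
    binary indicator set M of the model); garbage categories found there are
    kept separately and never enter M.
    """

    record: DeathRecord
    underlying_cat: str
    part1_cats: frozenset[str]
    garbage_contrib: frozenset[str]

    def indicator_vector(self, cause_list: CauseList = DEFAULT_CAUSE_LIST) -> np.ndarray:
        m = np.zeros(len(cause_list), dtype=np.int8)
        for cat in self.part1_cats:
            m[cause_list.index(cat)] = 1
        return m


class RecordValidationError(ValueError):
    pass


@dataclass
class RejectReport:
    """Per-row rejection reasons collected while reading micro-data."""

    rejects: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row_number: int, reason: str) -> None:
        self.rejects.append((row_number, reason))

    def __len__(self) -> int:
        return len(self.rejects)


def _parse_contributing(cell: str, revision: int) -> tuple[ContributingEntry, ...]:
    if not cell:
        return ()
    entries = []
    for triplet in cell.split(";"):
        parts = triplet.split(":")
        if len(parts) != 3:
            raise RecordValidationError(f"bad contributing triplet {triplet!r}")
        line, position = int(parts[0]), int(parts[1])
        if not 1 <= line <= 6:
            raise RecordValidationError(f"line out of range: {line}")
        if position < 1:
            raise RecordValidationError(f"position out of range: {position}")
        entries.append(ContributingEntry(line, position, normalize_icd(parts[2], revision)))
    return tuple(entries)


def _parse_row(row: dict[str, str], check_era: bool) -> DeathRecord:
    revision = int(row["revision"])
    if revision not in (9, 10):
        raise RecordValidationError(f"revision must be 9 or 10: {row['revision']!r}")
    year = int(row["year"])
    if check_era:
        lo, hi = REVISION_ERAS[revision]
        if not lo <= year <= hi:
            raise RecordValidationError(f"year {year} outside ICD{revision} era {lo}-{hi}")
    age = int(row["age"])
    if age < 0:
        raise RecordValidationError(f"negative age: {age}")
    sex = row["sex"].strip().lower()
    if sex not in SEXES:
        raise RecordValidationError(f"invalid sex {row['sex']!r}")
    place = row["place"].strip()
    if place not in PLACES:
        raise RecordValidationError(f"invalid place {row['place']!r}")
    return DeathRecord(
        id=row["id"],
        year=year,
        age=age,
        sex=sex,
        state=row["state"].strip(),
        race=row["race"].strip(),
        place=place,
        revision=revision,
        underlying=normalize_icd(row["underlying"], revision),
        contributing=_parse_contributing(row["contributing"].strip(), revision),
    )


def read_records(
    path: str | Path,
    check_era: bool = True,
    max_reject_fraction: float = 0.05,
) -> tuple[list[DeathRecord], RejectReport]:
    """Read micro-data records from the delimited dialect.

    Malformed rows are collected in the reject report with reasons; if more
    than ``max_reject_fraction`` of rows are rejected the whole read fails.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_records(text, check_era=check_era, max_reject_fraction=max_reject_fraction)


def parse_records(
    text: str,
    check_era: bool = True,
    max_reject_fraction: float = 0.05,
) -> tuple[list[DeathRecord], RejectReport]:
    first_line = text.splitlines()[0] if text else ""
    delim = "\t" if "\t" in first_line else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None or set(MICRODATA_HEADER) - set(reader.fieldnames):
        raise RecordValidationError(
            f"micro-data file must have header columns {MICRODATA_HEADER}"
        )
    records: list[DeathRecord] = []
    report = RejectReport()
    total = 0
    for i, row in enumerate(reader, start=2):
        total += 1
        try:
            records.append(_parse_row(row, check_era))
        except (RecordValidationError, ValueError) as exc:
            report.add(i, str(exc))
    if total and len(report) / total > max_reject_fraction:
        raise RecordValidationError(
            f"{len(report)}/{total} rows rejected "
            f"(> {max_reject_fraction:.0%}); first: {report.rejects[:3]}"
        )
    return records, report


def write_records(records: list[DeathRecord], path: str | Path) -> None:
    """Write records in the same dialect ``read_records`` consumes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MICRODATA_HEADER)
        for r in records:
            contributing = ";".join(
                f"{e.line}:{e.position}:{e.code}" for e in r.contributing
            )
            writer.writerow(
                [r.id, r.year, r.age, r.sex, r.state, r.race, r.place,
                 r.revision, r.underlying, contributing]
            )


def part1_codes(record: DeathRecord) -> list[ContributingEntry]:
    """Contributing entries on lines 1-5, in (line, position) order.

    Line-6 (Part II) entries are excluded: they mark conditions contributing
    to death but not in the causal chain, and never enter the model.
    """
    return sorted(
        (e for e in record.contributing if e.line <= 5),
        key=lambda e: (e.line, e.position),
    )


def categorize(
    record: DeathRecord,
    cause_map: CauseMap,
    strict: bool = True,
    cause_list: CauseList = DEFAULT_CAUSE_LIST,
) -> CategorizedRecord:
    """Condense a record's ICD codes into categories.

    The underlying code maps to ``underlying_cat``; the distinct valid causes
    on lines 1-5 become the indicator set M; garbage categories on lines 1-5
    are recorded separately (they drive training-set membership but are not
    covariates).
    """
    underlying_cat = map_code(record.underlying, cause_map, strict=strict)
    part1: set[str] = set()
    garbage: set[str] = set()
    for entry in part1_codes(record):
        cat = map_code(entry.code, cause_map, strict=strict)
        (garbage if is_garbage(cat) else part1).add(cat)
    return CategorizedRecord(
        record=record,
        underlying_cat=underlying_cat,
        part1_cats=frozenset(part1),
        garbage_contrib=frozenset(garbage),
    )
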