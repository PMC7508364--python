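"""Activity-record data model and delimited-text I/O.

The unit of analysis is the (region, ward, year) aggregate published
annually by the Italian Ministry of Health from hospital discharge report
forms: average available beds over the year, patients discharged in the
year, and total inpatient days of all patients.  ``ActivityTable`` wraps a
pandas DataFrame with that schema; ``ActivityRecord`` is the strict per-row
view.  Validation violations on a parsed table are data (a report), not
exceptions, so that a dirty source file can be inspected; schema problems
(missing column, duplicate key, unparsable number) are always raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import (
    InvariantViolationError,
    MixedYearsError,
    RowParseError,
    SchemaError,
    UniquenessError,
    UnknownWardWarning,
)

__all__ = [
    "COLUMNS",
    "WARD_CODES",
    "ActivityRecord",
    "ActivityTable",
    "Violation",
    "read_activity_csv",
    "write_activity_csv",
    "validate_records",
    "aggregate",
]

COLUMNS = ("region", "ward", "year", "beds", "discharges", "inpatient_days")
KEY = ("region", "ward", "year")

#: Controlled ward vocabulary: the hospital disciplines covering ~90% of
#: hospitalization complexity in the national publication, plus "all" for
#: whole-hospital rows.  Unknown codes are accepted with a warning — the
#: Ministry list may extend.
WARD_CODES = frozenset(
    {
        "all",
        "general_medicine",
        "general_surgery",
        "orthopaedics_traumatology",
        "obstetrics_gynaecology",
        "rehabilitation",
        "cardiology",
        "long_term_care",
        "neurology",
        "paediatrics",
        "geriatrics",
        "urology",
        "psychiatry",
        "pneumology",
        "oncology",
        "infectious_diseases",
        "neurosurgery",
        "intensive_care",
        "otolaryngology",
        "neonatology",
        "nephrology",
        "neuro_rehabilitation",
        "gastroenterology",
    }
)


@dataclass(frozen=True)
class ActivityRecord:
    """One validated (region, ward, year) aggregate.

    Construction enforces the invariants: non-negative counts, and — since
    every counted stay lasts at least one day — ``inpatient_days >=
    discharges`` whenever any patient was discharged.
    """

    region: str
    ward: str
    year: int
    beds: float
    discharges: int
    inpatient_days: int

    def __post_init__(self) -> None:
        for rule in _record_violations(self):
            raise InvariantViolationError(f"{self.key()}: {rule}")
        if self.ward not in WARD_CODES:
            warnings.warn(
                f"unknown ward code {self.ward!r}", UnknownWardWarning, stacklevel=3
            )

    def key(self) -> tuple[str, str, int]:
        return (self.region, self.ward, self.year)


@dataclass(frozen=True)
class Violation:
    """One invariant violation in a table: which record, which rule."""

    region: str
    ward: str
    year: int
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.region}, {self.ward}, {self.year}): {self.rule}"


def _record_violations(rec) -> list[str]:
    out = []
    if rec.beds < 0:
        out.append("beds must be >= 0")
    if rec.discharges < 0:
        out.append("discharges must be >= 0")
    if rec.inpatient_days < 0:
        out.append("inpatient_days must be >= 0")
    if rec.discharges > 0 and rec.inpatient_days < rec.discharges:
        out.append("inpatient_days < discharges (every stay lasts >= 1 day)")
    return out


@dataclass
class ActivityTable:
    """A non-empty collection of activity rows plus a provenance label."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        if len(self.df) == 0:
            raise SchemaError("activity table is empty")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)
        dup = self.df.duplicated(subset=list(KEY))
        if dup.any():
            keys = self.df.loc[dup, list(KEY)].itertuples(index=False, name=None)
            raise UniquenessError(
                "duplicate (region, ward, year): " + "; ".join(map(str, keys))
            )

    @classmethod
    def from_records(
        cls, records: Iterable[ActivityRecord], provenance: str = ""
    ) -> "ActivityTable":
        rows = [
            (r.region, r.ward, r.year, r.beds, r.discharges, r.inpatient_days)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)), provenance)

    def records(self) -> Iterator[ActivityRecord]:
        """Strict per-row view; raises on any invalid row."""
        for row in self.df.itertuples(index=False):
            yield ActivityRecord(
                str(row.region),
                str(row.ward),
                int(row.year),
                float(row.beds),
                int(row.discharges),
                int(row.inpatient_days),
            )

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, *, region=None, ward=None, year=None) -> "ActivityTable":
        """Filter by any combination of key fields (exact match)."""
        df = self.df
        if region is not None:
            df = df[df["region"] == region]
        if ward is not None:
            df = df[df["ward"] == ward]
        if year is not None:
            df = df[df["year"] == year]
        return ActivityTable(df.copy(), self.provenance)


def _parse_number(raw: str, kind: str, line: int, column: str):
    """Parse one cell, accepting both '.' and ',' as the decimal mark."""
    text = raw.strip().replace(" ", "").replace(" ", "")
    if "," in text and "." not in text:
        text = text.replace(",", ".")
    try:
        value = float(text)
    except ValueError:
        raise RowParseError(
            f"line {line}: cannot parse {column}={raw!r} as a number", line=line
        ) from None
    if kind == "int":
        if value != int(value):
            raise RowParseError(
                f"line {line}: {column}={raw!r} is not an integer count", line=line
            )
        return int(value)
    return value


def read_activity_csv(
    path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
    provenance: str | None = None,
    validate: bool = True,
) -> ActivityTable:
    """Read an activity CSV (`region,ward,year,beds,discharges,inpatient_days`).

    The reader is liberal about the decimal mark: decimal-comma cells
    (Italian convention) are parsed regardless of ``decimal``, which exists
    to document the dialect of the source.  Row order is preserved.

    Raises
    ------
    SchemaError
        empty file or missing required column.
    RowParseError
        unparsable cell, reported with its 1-based line number.
    UniquenessError
        duplicate (region, ward, year).
    InvariantViolationError
        only when ``validate=True`` and a row breaks a record invariant.
    """
    del decimal  # both marks are always accepted; kept for dialect symmetry
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header)") from None
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise SchemaError(f"{path}: no data rows")

    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        d = dict(zip(raw.columns, row))
        rows.append(
            (
                str(d["region"]).strip(),
                str(d["ward"]).strip(),
                _parse_number(d["year"], "int", line, "year"),
                _parse_number(d["beds"], "float", line, "beds"),
                _parse_number(d["discharges"], "int", line, "discharges"),
                _parse_number(d["inpatient_days"], "int", line, "inpatient_days"),
            )
        )
    table = ActivityTable(
        pd.DataFrame(rows, columns=list(COLUMNS)),
        provenance if provenance is not None else str(path),
    )
    if validate:
        report = validate_records(table)
        if report:
            raise InvariantViolationError(
                "; ".join(str(v) for v in report[:10])
                + ("" if len(report) <= 10 else f" (+{len(report) - 10} more)")
            )
    unknown = sorted(set(table.df["ward"]) - WARD_CODES)
    if unknown:
        warnings.warn(
            f"unknown ward code(s): {', '.join(unknown)}",
            UnknownWardWarning,
            stacklevel=2,
        )
    return table


def write_activity_csv(table: ActivityTable, path) -> None:
    """Write a table back to CSV; the writer always emits '.' decimals."""
    table.df.to_csv(path, index=False)


def validate_records(table: ActivityTable) -> list[Violation]:
    """Check every record invariant; an empty report means the table is clean."""
    report: list[Violation] = []
    for row in table.df.itertuples(index=False):
        for rule in _record_violations(row):
            report.append(
                Violation(str(row.region), str(row.ward), int(row.year), rule)
            )
    return report


def aggregate(
    table: ActivityTable,
    by: Sequence[str],
    *,
    allow_mixed_years: bool = False,
) -> ActivityTable:
    """Sum beds, discharges and inpatient days within groups.

    ``by`` is a subset of {region, ward, year}; marginalised region/ward
    come back as ``"all"``.  Pooling several calendar years is almost always
    an accident, so marginalising ``year`` over a multi-year table raises
    unless ``allow_mixed_years`` is set (the pooled rows then carry year -1).
    """
    by = list(by)
    bad = [k for k in by if k not in KEY]
    if bad:
        raise SchemaError(f"cannot group by {bad}; keys are {KEY}")
    df = table.df.copy()
    years = df["year"].unique()
    if "year" not in by and len(years) > 1 and not allow_mixed_years:
        raise MixedYearsError(
            f"table spans years {sorted(map(int, years))}; include 'year' in the "
            "grouping, filter first, or pass allow_mixed_years=True"
        )
    if by:
        grouped = (
            df.groupby(by, sort=False, as_index=False)[
                ["beds", "discharges", "inpatient_days"]
            ].sum()
        )
    else:
        grouped = df[["beds", "discharges", "inpatient_days"]].sum().to_frame().T
    if "region" not in by:
        grouped["region"] = "all"
    if "ward" not in by:
        grouped["ward"] = "all"
    if "year" not in by:
        grouped["year"] = int(years[0]) if len(years) == 1 else -1
    grouped = grouped.loc[:, list(COLUMNS)]
    grouped["year"] = grouped["year"].astype(int)
    grouped["discharges"] = grouped["discharges"].astype(int)
    grouped["inpatient_days"] = grouped["inpatient_days"].astype(int)
    return ActivityTable(grouped, provenance=f"{table.provenance} [aggregated by {by}]")
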