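"""Study-level data model and CSV I/O for case-control genotype tables.

A *study* is one independent case-control comparison at a biallelic SNP
(major allele G, minor allele C).  Each study carries its declared arm
sizes and, when the source article published them, the genotype counts
(GG / GC / CC) per arm.  Studies whose counts were never released may
instead carry a precomputed log odds ratio and its standard error so
that they can still enter an allele-model pooling.

The bundled fixture ``table1_rs9349407.csv`` reproduces, verbatim, the
published per-study table for the CD2AP rs9349407 polymorphism in
Chinese Alzheimer's-disease case-control studies (11 studies, 4,173
cases / 6,137 controls).  Several of its printed genotype rows do not
sum to the declared arm totals; :func:`validate_study` flags these as
warnings rather than silently correcting them, because the correct
figures are not recoverable from the publication.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from string import ascii_lowercase
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "CohortTable",
    "ValidationFinding",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "CSV_COLUMNS",
    "load_studies",
    "write_studies",
    "load_fixture",
    "validate_study",
    "validate_table",
    "cohort_totals",
    "FIXTURE_NAME",
]

#: CSV schema, in column order.  ``log_or`` and ``se`` are optional columns.
CSV_COLUMNS = [
    "study_id", "population", "n_case", "n_control",
    "case_gg", "case_gc", "case_cc",
    "ctrl_gg", "ctrl_gc", "ctrl_cc",
    "log_or", "se",
]
_REQUIRED_COLUMNS = CSV_COLUMNS[:10]

FIXTURE_NAME = "table1_rs9349407.csv"


class SchemaError(ValueError):
    """The input file does not match the documented CSV schema."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


class ValidationError(ValueError):
    """Raised when error-severity findings block an analysis."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one study arm at a biallelic G/C SNP."""

    gg: int
    gc: int
    cc: int

    def total(self) -> int:
        return self.gg + self.gc + self.cc

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.gg, self.gc, self.cc)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: arm totals plus optional counts/effect.

    A record without genotype counts can only enter an analysis when both
    ``precomputed_log_or`` and ``precomputed_se`` are present (and then only
    for the allele model, whose scale they are assumed to be on).
    """

    study_id: str
    population: str
    n_case: int
    n_control: int
    case_genotypes: Optional[GenotypeCounts] = None
    control_genotypes: Optional[GenotypeCounts] = None
    precomputed_log_or: Optional[float] = None
    precomputed_se: Optional[float] = None

    @property
    def has_genotypes(self) -> bool:
        return self.case_genotypes is not None and self.control_genotypes is not None

    @property
    def has_precomputed(self) -> bool:
        return self.precomputed_log_or is not None and self.precomputed_se is not None


@dataclass
class CohortTable:
    """An ordered collection of studies forming one meta-analysis input."""

    studies: list[StudyRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.studies)

    def __getitem__(self, i):
        return self.studies[i]

    def get(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)


@dataclass(frozen=True)
class ValidationFinding:
    """One data-quality finding; errors block analysis, warnings do not."""

    study_id: str
    severity: str  # "warning" | "error"
    message: str
    observed: Optional[float] = None
    expected: Optional[float] = None


# ---------------------------------------------------------------------------
# parsing helpers

_NA_STRINGS = {"", "na", "n/a", "nan"}


def _is_na(cell: str) -> bool:
    return cell.strip().lower() in _NA_STRINGS


def _parse_int(cell: str, row: int, col: str) -> int:
    text = cell.strip()
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"row {row}, column {col!r}: expected an integer count, got {text!r}"
        ) from None


def _parse_optional_int(cell: str, row: int, col: str) -> Optional[int]:
    return None if _is_na(cell) else _parse_int(cell, row, col)


def _parse_optional_float(cell: str, row: int, col: str) -> Optional[float]:
    if _is_na(cell):
        return None
    try:
        return float(cell.strip())
    except ValueError:
        raise ParseError(
            f"row {row}, column {col!r}: expected a real number, got {cell!r}"
        ) from None


def _arm_counts(cells: dict[str, Optional[int]], row: int, arm: str) -> Optional[GenotypeCounts]:
    values = list(cells.values())
    if all(v is None for v in values):
        return None
    if any(v is None for v in values):
        missing = [c for c, v in cells.items() if v is None]
        raise ParseError(
            f"row {row}: {arm} genotype counts are partially missing "
            f"(columns {missing}); provide all three or none"
        )
    return GenotypeCounts(*values)  # type: ignore[arg-type]


def _disambiguate_ids(ids: list[str]) -> list[str]:
    """Suffix duplicate study ids with _a, _b, ... in row order."""
    counts = Counter(ids)
    seen: Counter = Counter()
    out = []
    for sid in ids:
        if counts[sid] > 1:
            out.append(f"{sid}_{ascii_lowercase[seen[sid]]}")
            seen[sid] += 1
        else:
            out.append(sid)
    return out


def load_studies(path, format: str = "csv") -> CohortTable:
    """Read a study table from ``path`` into a :class:`CohortTable`.

    "NA" (case-insensitive) and empty cells denote absent values.  Duplicate
    ``study_id`` values are disambiguated with ``_a``/``_b`` suffixes in row
    order so that every study has a unique key.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    has_effect_cols = "log_or" in df.columns and "se" in df.columns
    studies: list[StudyRecord] = []
    raw_ids: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cells = dict(zip(df.columns, row))
        raw_ids.append(str(cells["study_id"]).strip())
        case_g = _arm_counts(
            {c: _parse_optional_int(cells[c], i, c) for c in ("case_gg", "case_gc", "case_cc")},
            i, "case",
        )
        ctrl_g = _arm_counts(
            {c: _parse_optional_int(cells[c], i, c) for c in ("ctrl_gg", "ctrl_gc", "ctrl_cc")},
            i, "control",
        )
        studies.append(StudyRecord(
            study_id="",  # filled after disambiguation
            population=str(cells["population"]).strip(),
            n_case=_parse_int(cells["n_case"], i, "n_case"),
            n_control=_parse_int(cells["n_control"], i, "n_control"),
            case_genotypes=case_g,
            control_genotypes=ctrl_g,
            precomputed_log_or=_parse_optional_float(cells["log_or"], i, "log_or") if has_effect_cols else None,
            precomputed_se=_parse_optional_float(cells["se"], i, "se") if has_effect_cols else None,
        ))
    unique_ids = _disambiguate_ids(raw_ids)
    studies = [replace(s, study_id=sid) for s, sid in zip(studies, unique_ids)]
    return CohortTable(studies=studies, label=Path(str(path)).stem)


def write_studies(table: CohortTable, path) -> None:
    """Write a :class:`CohortTable` in the documented CSV schema.

    Absent values are written as empty cells, so ``write_studies`` followed
    by :func:`load_studies` round-trips every field exactly.
    """
    def cell(v) -> str:
        # stringify up front so pandas never coerces int columns to floats
        if v is None:
            return ""
        return repr(v) if isinstance(v, float) else str(v)

    rows = []
    for s in table.studies:
        cg = s.case_genotypes.as_tuple() if s.case_genotypes else (None,) * 3
        kg = s.control_genotypes.as_tuple() if s.control_genotypes else (None,) * 3
        rows.append({
            "study_id": cell(s.study_id),
            "population": cell(s.population),
            "n_case": cell(s.n_case),
            "n_control": cell(s.n_control),
            "case_gg": cell(cg[0]), "case_gc": cell(cg[1]), "case_cc": cell(cg[2]),
            "ctrl_gg": cell(kg[0]), "ctrl_gc": cell(kg[1]), "ctrl_cc": cell(kg[2]),
            "log_or": cell(s.precomputed_log_or),
            "se": cell(s.precomputed_se),
        })
    pd.DataFrame(rows, columns=CSV_COLUMNS, dtype=object).to_csv(path, index=False)


def load_fixture() -> CohortTable:
    """Load the bundled verbatim rs9349407 study table (11 studies)."""
    ref = resources.files("admeta").joinpath(f"data/{FIXTURE_NAME}")
    with resources.as_file(ref) as p:
        table = load_studies(p)
    table.label = Path(FIXTURE_NAME).stem
    return table


# ---------------------------------------------------------------------------
# validation

def validate_study(record: StudyRecord) -> list[ValidationFinding]:
    """Check one study's internal consistency.

    Errors: negative counts or arm totals, half-specified precomputed effect,
    non-positive precomputed SE.  Warnings: genotype counts present but their
    sum differs from the declared arm total (common in published tables with
    incomplete genotyping, and present in the bundled fixture).
    """
    findings: list[ValidationFinding] = []
    sid = record.study_id

    for name, n in (("n_case", record.n_case), ("n_control", record.n_control)):
        if n < 0:
            findings.append(ValidationFinding(sid, "error", f"{name} is negative", observed=n, expected=0))

    for arm, geno, declared in (
        ("case", record.case_genotypes, record.n_case),
        ("control", record.control_genotypes, record.n_control),
    ):
        if geno is None:
            continue
        if min(geno.as_tuple()) < 0:
            findings.append(ValidationFinding(
                sid, "error", f"negative {arm} genotype count {geno.as_tuple()}",
                observed=min(geno.as_tuple()), expected=0,
            ))
        elif geno.total() != declared:
            findings.append(ValidationFinding(
                sid, "warning",
                f"{arm} genotype total {geno.total()} differs from declared "
                f"n_{arm} {declared}",
                observed=geno.total(), expected=declared,
            ))

    if (record.precomputed_log_or is None) != (record.precomputed_se is None):
        findings.append(ValidationFinding(
            sid, "error", "precomputed effect requires both log_or and se"))
    elif record.precomputed_se is not None and record.precomputed_se <= 0:
        findings.append(ValidationFinding(
            sid, "error", "precomputed se must be positive",
            observed=record.precomputed_se, expected=0))
    return findings


def validate_table(table: CohortTable) -> list[ValidationFinding]:
    """Validate every study; findings keep the table's row order."""
    out: list[ValidationFinding] = []
    for s in table.studies:
        out.extend(validate_study(s))
    return out


def cohort_totals(table: CohortTable) -> tuple[int, int]:
    """Total cases and controls across all studies."""
    return (
        sum(s.n_case for s in table.studies),
        sum(s.n_control for s in table.studies),
    )
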