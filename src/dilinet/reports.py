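"""Reading, validating, deduplicating and filtering spontaneous reports.

The report table dialect is a UTF-8 CSV with header::

    report_id,case_id,case_version,receipt_date,drug_name,drug_role,pt_code,
    sex,age_years,report_year,reporter,outcome,therapy_start_date,event_onset_date

One row is one report-drug-event assertion; a report (one ``report_id``) is
one version of a case (one ``case_id``), and spans several rows when it
names several drugs or events. Empty string means missing. Drug roles
follow FAERS: PS (primary suspect, "major suspicious"), SS (secondary
suspect), C (concomitant), I (interacting).

Deduplication keeps, per case, the single latest version: highest
``case_version``, ties broken by latest ``receipt_date`` then
lexicographically greatest ``report_id``. This mirrors the convention that
a follow-up FAERS case version supersedes earlier ones.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._common import (
    ParseError,
    SchemaError,
    logger,
    normalize_drug_name,
)

REPORT_COLUMNS = (
    "report_id",
    "case_id",
    "case_version",
    "receipt_date",
    "drug_name",
    "drug_role",
    "pt_code",
    "sex",
    "age_years",
    "report_year",
    "reporter",
    "outcome",
    "therapy_start_date",
    "event_onset_date",
)

DRUG_ROLES = ("PS", "SS", "C", "I")
SEXES = ("F", "M", "")
REPORTERS = ("consumer", "health_professional", "unknown")
#: Outcome menu of the descriptive tables; missing is the empty string.
OUTCOMES = ("Life-Threatening", "Hospitalization", "Disability", "Death", "Other", "")

_ROLE_PRECEDENCE = {"PS": 0, "SS": 1, "C": 2, "I": 3}


@dataclass(frozen=True)
class ReportRecord:
    """One validated report-drug-event assertion."""

    report_id: str
    case_id: str
    case_version: int
    receipt_date: str
    drug_name: str
    drug_role: str
    pt_code: str
    sex: str
    age_years: float | None
    report_year: int
    reporter: str
    outcome: str
    therapy_start_date: str
    event_onset_date: str


@dataclass
class RowIssue:
    """A rejected input row with its 1-based line number and reason."""

    line: int
    reason: str


@dataclass
class CleanReportSet:
    """Deduplicated assertions plus provenance counters.

    ``frame`` holds one row per retained (report, drug, PT) assertion with
    an extra ``drug_norm`` column (normalized drug name). ``counters`` keys
    ``rows_read``, ``rows_dedup_dropped``, ``rows_collapsed`` and
    ``rows_retained`` always sum: read = retained + dropped + collapsed.
    """

    frame: pd.DataFrame
    counters: dict[str, int] = field(default_factory=dict)

    @property
    def records(self) -> list[ReportRecord]:
        return [_row_to_record(row) for row in self.frame.itertuples(index=False)]

    @property
    def n_reports(self) -> int:
        """Number of unique retained reports (the counting unit)."""
        return int(self.frame["report_id"].nunique())

    def report_ids(self) -> pd.Index:
        return pd.Index(self.frame["report_id"].unique())


def _row_to_record(row) -> ReportRecord:
    return ReportRecord(
        report_id=row.report_id,
        case_id=row.case_id,
        case_version=int(row.case_version),
        receipt_date=row.receipt_date,
        drug_name=row.drug_name,
        drug_role=row.drug_role,
        pt_code=row.pt_code,
        sex=row.sex,
        age_years=None if row.age_years == "" else float(row.age_years),
        report_year=int(row.report_year),
        reporter=row.reporter,
        outcome=row.outcome,
        therapy_start_date=row.therapy_start_date,
        event_onset_date=row.event_onset_date,
    )


def _parse_date(value: str, column: str) -> str:
    v = value.strip()
    if v == "":
        return ""
    try:
        _dt.date.fromisoformat(v)
    except ValueError:
        raise ValueError(f"{column}: not an ISO date: {v!r}") from None
    return v


def _validate_row(row: dict[str, str]) -> ReportRecord:
    rid = row["report_id"].strip()
    if not rid:
        raise ValueError("report_id: must be nonempty")
    cid = row["case_id"].strip()
    if not cid:
        raise ValueError("case_id: must be nonempty")
    try:
        version = int(row["case_version"])
    except ValueError:
        raise ValueError(f"case_version: not an integer: {row['case_version']!r}") from None
    if version < 1:
        raise ValueError(f"case_version: must be >= 1, got {version}")
    receipt = _parse_date(row["receipt_date"], "receipt_date")
    drug = row["drug_name"].strip()
    if not drug:
        raise ValueError("drug_name: must be nonempty")
    role = row["drug_role"].strip()
    if role not in DRUG_ROLES:
        raise ValueError(f"drug_role: unknown role code {role!r}")
    pt = row["pt_code"].strip()
    if not pt:
        raise ValueError("pt_code: must be nonempty")
    sex = row["sex"].strip()
    if sex not in SEXES:
        raise ValueError(f"sex: must be F, M or empty, got {sex!r}")
    age_raw = row["age_years"].strip()
    age: float | None = None
    if age_raw:
        try:
            age = float(age_raw)
        except ValueError:
            raise ValueError(f"age_years: not a number: {age_raw!r}") from None
        if age < 0:
            raise ValueError(f"age_years: negative: {age}")
    try:
        year = int(row["report_year"])
    except ValueError:
        raise ValueError(f"report_year: not an integer: {row['report_year']!r}") from None
    reporter = row["reporter"].strip()
    if reporter not in REPORTERS:
        raise ValueError(f"reporter: unknown category {reporter!r}")
    outcome = row["outcome"].strip()
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome: unknown category {outcome!r}")
    start = _parse_date(row["therapy_start_date"], "therapy_start_date")
    onset = _parse_date(row["event_onset_date"], "event_onset_date")
    if start and onset and start > onset:
        raise ValueError(
            f"therapy_start_date {start} after event_onset_date {onset}"
        )
    return ReportRecord(
        report_id=rid,
        case_id=cid,
        case_version=version,
        receipt_date=receipt,
        drug_name=drug,
        drug_role=role,
        pt_code=pt,
        sex=sex,
        age_years=age,
        report_year=year,
        reporter=reporter,
        outcome=outcome,
        therapy_start_date=start,
        event_onset_date=onset,
    )


def read_reports_detailed(
    path: str | Path, max_bad_fraction: float = 0.05
) -> tuple[list[ReportRecord], list[RowIssue]]:
    """Read a report table, returning validated records and rejected rows.

    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`ParseError` when more than ``max_bad_fraction`` of data rows
    fail validation.
    """
    records: list[ReportRecord] = []
    issues: list[RowIssue] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REPORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns: {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_validate_row(row))
            except ValueError as exc:
                issues.append(RowIssue(line=lineno, reason=str(exc)))
    total = len(records) + len(issues)
    if total and len(issues) / total > max_bad_fraction:
        raise ParseError(
            f"{path}: {len(issues)} of {total} rows invalid "
            f"(> {max_bad_fraction:.0%}); first: line {issues[0].line}: {issues[0].reason}"
        )
    for issue in issues:
        logger.warning("%s: row rejected at line %d: %s", path, issue.line, issue.reason)
    return records, issues


def read_reports(path: str | Path, max_bad_fraction: float = 0.05) -> list[ReportRecord]:
    """Read a report table; rejected rows are logged (see
    :func:`read_reports_detailed` to inspect them)."""
    records, _ = read_reports_detailed(path, max_bad_fraction)
    return records


def records_to_frame(records: list[ReportRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "report_id": r.report_id,
                "case_id": r.case_id,
                "case_version": r.case_version,
                "receipt_date": r.receipt_date,
                "drug_name": r.drug_name,
                "drug_role": r.drug_role,
                "pt_code": r.pt_code,
                "sex": r.sex,
                "age_years": "" if r.age_years is None else r.age_years,
                "report_year": r.report_year,
                "reporter": r.reporter,
                "outcome": r.outcome,
                "therapy_start_date": r.therapy_start_date,
                "event_onset_date": r.event_onset_date,
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def deduplicate(
    records: list[ReportRecord] | pd.DataFrame,
    synonyms: dict[str, str] | None = None,
) -> CleanReportSet:
    """Keep one version per case and collapse repeated assertions.

    Per ``case_id`` the retained report is the one with the highest
    ``case_version`` (ties: latest ``receipt_date``, then greatest
    ``report_id``); all rows of superseded versions are dropped. Within the
    retained report, repeated (drug, PT) assertions collapse to one row,
    keeping the strongest drug role (PS > SS > C > I). Deterministic and
    idempotent.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame = frame.reset_index(drop=True)
    rows_read = len(frame)
    if rows_read == 0:
        empty = frame.copy()
        empty["drug_norm"] = pd.Series(dtype=str)
        return CleanReportSet(
            frame=empty,
            counters={
                "rows_read": 0,
                "rows_dedup_dropped": 0,
                "rows_collapsed": 0,
                "rows_retained": 0,
            },
        )

    # ISO dates sort lexicographically in chronological order; missing
    # receipt dates (empty string) sort as oldest.
    keys = frame[["case_id", "case_version", "receipt_date", "report_id"]].copy()
    keys["case_version"] = keys["case_version"].astype(int)
    winners = (
        keys.sort_values(
            ["case_id", "case_version", "receipt_date", "report_id"],
            kind="mergesort",
        )
        .groupby("case_id", sort=False)["report_id"]
        .last()
    )
    kept = frame[frame["report_id"].isin(set(winners))].copy()
    rows_dedup_dropped = rows_read - len(kept)

    kept["drug_norm"] = [
        normalize_drug_name(n, synonyms) for n in kept["drug_name"]
    ]
    prec = kept["drug_role"].map(_ROLE_PRECEDENCE)
    kept = (
        kept.assign(_prec=prec)
        .sort_values(["report_id", "drug_norm", "pt_code", "_prec"], kind="mergesort")
        .drop_duplicates(subset=["report_id", "drug_norm", "pt_code"], keep="first")
        .drop(columns="_prec")
    )
    rows_collapsed = rows_read - rows_dedup_dropped - len(kept)
    kept = kept.sort_index().reset_index(drop=True)
    return CleanReportSet(
        frame=kept,
        counters={
            "rows_read": rows_read,
            "rows_dedup_dropped": rows_dedup_dropped,
            "rows_collapsed": rows_collapsed,
            "rows_retained": len(kept),
        },
    )


def filter_primary_suspect(
    records: list[ReportRecord] | CleanReportSet,
    drug: str,
    synonyms: dict[str, str] | None = None,
) -> list[ReportRecord]:
    """Keep assertions naming ``drug`` (after normalization) with role PS.

    Rows carrying an unrecognized role code are excluded with a warning
    rather than failing the whole filter.
    """
    if not drug or not drug.strip():
        raise ValueError("drug: must be nonempty")
    target = normalize_drug_name(drug, synonyms)
    items = records.records if isinstance(records, CleanReportSet) else records
    out = []
    for r in items:
        if r.drug_role not in DRUG_ROLES:
            logger.warning("report %s: unknown drug role %r, row excluded", r.report_id, r.drug_role)
            continue
        if r.drug_role == "PS" and normalize_drug_name(r.drug_name, synonyms) == target:
            out.append(r)
    return out


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Read a two-column ``alias,canonical`` CSV into a normalized map."""
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != ["alias", "canonical"]:
            raise SchemaError(f"{path}: expected header alias,canonical")
        for lineno, row in enumerate(reader, start=2):
            alias = normalize_drug_name(row["alias"])
            canonical = normalize_drug_name(row["canonical"])
            if not alias or not canonical:
                raise ParseError(f"{path}: empty alias or canonical", line=lineno)
            out[alias] = canonical
    return out


def multi_drug_cases(clean: CleanReportSet, study_drugs: list[str],
                     synonyms: dict[str, str] | None = None) -> dict[str, list[str]]:
    """Diagnostic: cases whose retained report names >= 2 distinct study
    drugs as primary suspect. Such cases are reported but never removed."""
    targets = {normalize_drug_name(d, synonyms) for d in study_drugs}
    df = clean.frame
    ps = df[(df["drug_role"] == "PS") & (df["drug_norm"].isin(targets))]
    per_case = ps.groupby("case_id")["drug_norm"].agg(lambda s: sorted(set(s)))
    return {case: drugs for case, drugs in per_case.items() if len(drugs) >= 2}
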