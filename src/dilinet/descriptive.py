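"""Cohort characterization: categorical breakdowns and time-to-onset.

Summaries are computed over unique retained reports of one drug (primary
suspect) restricted to a liver-injury PT set, mirroring the structure of a
spontaneous-report characteristics table: sex, age, report-year bands,
reporter type, outcome, plus onset-interval quartiles.

Quartiles use the median-of-halves convention: q1 and q3 are the medians
of the lower and upper halves of the sorted data, the overall median being
excluded from both halves when n is odd (so three points {10, 20, 30}
yield exactly (10, 20, 30)). This is one fixed, documented convention;
spontaneous-report papers rarely state theirs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from ._common import logger, normalize_drug_name, round_half_up
from .reports import CleanReportSet, OUTCOMES, REPORTERS


def percentage(part: float, whole: float, ndigits: int = 2) -> float:
    """Half-up percentage of ``part`` in ``whole`` (0.0 when whole == 0)."""
    if whole == 0:
        return 0.0
    return round_half_up(100.0 * part / whole, ndigits)


def quartiles_by_halves(values: list[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by the median-of-halves rule.

    For odd n the overall median is excluded from both halves; a single
    value is its own median and both quartiles.
    """
    if not values:
        raise ValueError("quartiles_by_halves: empty input")
    xs = sorted(values)
    n = len(xs)

    def med(seq: list[float]) -> float:
        m = len(seq)
        mid = m // 2
        return float(seq[mid]) if m % 2 else (seq[mid - 1] + seq[mid]) / 2.0

    if n == 1:
        return float(xs[0]), float(xs[0]), float(xs[0])
    half = n // 2  # median excluded from the halves when n is odd
    return med(xs[:half]), med(xs), med(xs[n - half:])


@dataclass
class OnsetSummary:
    """Time-to-onset distribution in whole days."""

    n: int
    missing: int
    median: float | None
    q1: float | None
    q3: float | None


@dataclass
class CohortSummary:
    """Per-drug descriptive table over the event-restricted cohort."""

    drug: str
    n_reports: int                    # cohort size (drug x event-set reports)
    n_drug_reports: int               # all retained reports of the drug
    dili_fraction_pct: float          # cohort / all drug reports, 1 decimal
    sex: dict[str, dict[str, float]] = field(default_factory=dict)
    age: dict[str, float | int | None] = field(default_factory=dict)
    report_year: dict[str, dict[str, float]] = field(default_factory=dict)
    reporter: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome: dict[str, dict[str, float]] = field(default_factory=dict)
    onset: OnsetSummary | None = None

    def to_dict(self) -> dict:
        d = {
            "drug": self.drug,
            "n_reports": self.n_reports,
            "n_drug_reports": self.n_drug_reports,
            "dili_fraction_pct": self.dili_fraction_pct,
            "sex": self.sex,
            "age": self.age,
            "report_year": self.report_year,
            "reporter": self.reporter,
            "outcome": self.outcome,
        }
        if self.onset is not None:
            d["onset"] = vars(self.onset)
        return d


def _cohort_frames(clean: CleanReportSet, drug: str, dili_pt_set, synonyms):
    df = clean.frame
    target = normalize_drug_name(drug, synonyms)
    drug_ids = set(df.loc[(df["drug_role"] == "PS") & (df["drug_norm"] == target), "report_id"])
    event_ids = set(df.loc[df["pt_code"].isin(dili_pt_set), "report_id"])
    cohort_ids = drug_ids & event_ids
    # one demographic row per report
    per_report = df.drop_duplicates(subset="report_id").set_index("report_id")
    return per_report.loc[sorted(cohort_ids)], len(drug_ids)


def summarize_cohort(
    clean: CleanReportSet,
    drug: str,
    dili_pt_set: frozenset[str] | set[str],
    synonyms: dict[str, str] | None = None,
) -> CohortSummary:
    """Tabulate the characteristics of reports of ``drug`` carrying at
    least one PT from ``dili_pt_set``.

    Category percentages are over the cohort size (2 decimals, half-up);
    the event-record fraction is cohort size over all retained reports of
    the drug (1 decimal).
    """
    cohort, n_drug = _cohort_frames(clean, drug, dili_pt_set, synonyms)
    n = len(cohort)
    if n == 0:
        logger.warning("empty cohort for %s; summary is all zeros", drug)

    summary = CohortSummary(
        drug=drug,
        n_reports=n,
        n_drug_reports=n_drug,
        dili_fraction_pct=percentage(n, n_drug, 1),
    )

    sex_counts = {"F": 0, "M": 0, "missing": 0}
    for v in cohort["sex"]:
        sex_counts["missing" if v == "" else v] += 1
    summary.sex = {
        k: {"n": c, "pct": percentage(c, n)} for k, c in sex_counts.items()
    }

    ages = [float(v) for v in cohort["age_years"] if v != ""]
    if ages:
        q1, med, q3 = quartiles_by_halves(ages)
    else:
        q1 = med = q3 = None
    summary.age = {"n": len(ages), "missing": n - len(ages), "median": med, "q1": q1, "q3": q3}

    years = [int(v) for v in cohort["report_year"]]
    bands: dict[str, int] = {}
    for y in years:
        band = "before_2019" if y <= 2019 else str(y)
        bands[band] = bands.get(band, 0) + 1
    summary.report_year = {
        band: {"n": c, "pct": percentage(c, n)}
        for band, c in sorted(bands.items())
    }

    rep_counts = {r: 0 for r in REPORTERS}
    for v in cohort["reporter"]:
        rep_counts[v] += 1
    summary.reporter = {k: {"n": c, "pct": percentage(c, n)} for k, c in rep_counts.items()}

    out_counts = {(o if o else "Missing"): 0 for o in OUTCOMES}
    for v in cohort["outcome"]:
        out_counts["Missing" if v == "" else v] += 1
    summary.outcome = {k: {"n": c, "pct": percentage(c, n)} for k, c in out_counts.items()}

    summary.onset = time_to_onset(clean, drug, dili_pt_set, synonyms)
    return summary


def time_to_onset(
    clean: CleanReportSet,
    drug: str,
    dili_pt_set: frozenset[str] | set[str],
    synonyms: dict[str, str] | None = None,
) -> OnsetSummary:
    """Days from therapy start to event onset over the cohort.

    Reports missing either date — or, defensively, with a negative
    interval — are counted as missing rather than clamped.
    """
    cohort, _ = _cohort_frames(clean, drug, dili_pt_set, synonyms)
    onsets: list[float] = []
    missing = 0
    for start, onset in zip(cohort["therapy_start_date"], cohort["event_onset_date"]):
        if not start or not onset:
            missing += 1
            continue
        days = (_dt.date.fromisoformat(onset) - _dt.date.fromisoformat(start)).days
        if days < 0:
            logger.warning("negative onset interval (%d d) treated as missing", days)
            missing += 1
            continue
        onsets.append(float(days))
    if onsets:
        q1, med, q3 = quartiles_by_halves(onsets)
        return OnsetSummary(n=len(onsets), missing=missing, median=med, q1=q1, q3=q3)
    return OnsetSummary(n=0, missing=missing, median=None, q1=None, q3=None)
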