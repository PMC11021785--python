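"""Reporting odds ratio with Woolf confidence intervals and signal scans.

The 2x2 contingency table compares one drug against all other drugs in the
database at report level::

                         event PT-set    other events
    target drug               a               b
    all other drugs           c               d

ROR = (a*d)/(b*c); the Woolf interval is built on the log scale with
standard error sqrt(1/a + 1/b + 1/c + 1/d), so the point estimate is the
geometric mean of its bounds. When any cell is zero the Haldane–Anscombe
correction adds 0.5 to all four cells before estimation; the positivity
rule always uses the raw count a. A pair is a positive signal when
a >= 3 and the lower 95% CI bound exceeds 1.

Counting is at report level with ANY-match semantics: a retained report is
in the event margin if any of its PTs belongs to the query set, and in the
drug margin if any retained primary-suspect assertion names the drug. This
prevents one report being counted once per member PT of an SMQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._common import (
    DegenerateMarginError,
    DilinetError,
    logger,
    normalize_drug_name,
    round_half_up,
)
from .meddra import MedDRADict, expand_query
from .reports import CleanReportSet

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug x event-set pair."""

    a: int  # target drug, target event(s)
    b: int  # target drug, other events
    c: int  # other drugs, target event(s)
    d: int  # other drugs, other events

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalStats:
    """ROR point estimate with Woolf CI for one pair."""

    ror: float
    ci_low: float
    ci_high: float
    se_log: float
    n_reports: int
    corrected: bool


@dataclass(frozen=True)
class SignalResult:
    """One drug x code scan cell; ``stats`` is None when the pair's table
    had a degenerate margin (the error text is kept instead)."""

    drug: str
    level: str
    code: str
    name: str
    stats: SignalStats | None
    positive: bool
    error: str | None = None


def build_contingency(
    clean: CleanReportSet,
    drug: str,
    pt_set: frozenset[str] | set[str],
    synonyms: dict[str, str] | None = None,
) -> ContingencyTable:
    """Count the 2x2 table for ``drug`` against the PT set.

    ``clean`` must already be deduplicated; every retained report counts
    exactly once, so a + b + c + d equals the number of retained reports.
    """
    if not pt_set:
        raise ValueError("pt_set must be nonempty")
    target = normalize_drug_name(drug, synonyms)
    df = clean.frame
    ids = df["report_id"]
    drug_rows = (df["drug_role"] == "PS") & (df["drug_norm"] == target)
    event_rows = df["pt_code"].isin(pt_set)
    has_drug = set(ids[drug_rows])
    has_event = set(ids[event_rows])
    total = int(ids.nunique())
    a = len(has_drug & has_event)
    b = len(has_drug) - a
    c = len(has_event) - a
    d = total - a - b - c
    return ContingencyTable(a, b, c, d)


def compute_ror(t: ContingencyTable, z: float = Z_95) -> SignalStats:
    """Woolf-interval ROR for a 2x2 table.

    Raises :class:`DegenerateMarginError` when the drug (a+b) or comparator
    (c+d) margin is empty — no estimate is meaningful there. A single zero
    cell triggers the 0.5 continuity correction on all four cells.
    """
    if t.a + t.b == 0:
        raise DegenerateMarginError("drug margin empty (a + b = 0)")
    if t.c + t.d == 0:
        raise DegenerateMarginError("comparator margin empty (c + d = 0)")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = (
        (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5) if corrected else (t.a, t.b, t.c, t.d)
    )
    log_ror = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return SignalStats(
        ror=math.exp(log_ror),
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        se_log=se,
        n_reports=t.a,
        corrected=corrected,
    )


def detect_signal(s: SignalStats, min_count: int = 3) -> bool:
    """Positive signal rule: at least ``min_count`` reports and lower 95%
    CI bound of the ROR strictly above 1."""
    return s.n_reports >= min_count and s.ci_low > 1.0


def scan_signals(
    clean: CleanReportSet,
    drugs: list[str],
    d: MedDRADict,
    level: str,
    codes: list[str] | None = None,
    scope: str = "combined",
    min_count: int = 3,
    synonyms: dict[str, str] | None = None,
) -> list[SignalResult]:
    """One SignalResult per drug x code, expanded through the hierarchy.

    Negative results are retained with ``positive=False``; a pair whose
    table has a degenerate margin yields a result carrying the error text
    instead of aborting the scan. PT-level results are ordered by HLT name
    then PT name (the layout of printed PT signal tables); other levels by
    term name.
    """
    if codes is None:
        codes = d.codes_at_level(level)
    expansions = {code: expand_query(d, level, code, scope) for code in codes}

    results: list[SignalResult] = []
    for drug in drugs:
        for code in codes:
            pt_set = expansions[code]
            name = d.name_of(level, code)
            if not pt_set:
                results.append(
                    SignalResult(drug, level, code, name, None, False, error="empty expansion")
                )
                continue
            table = build_contingency(clean, drug, pt_set, synonyms)
            try:
                stats = compute_ror(table)
            except DilinetError as exc:
                logger.warning("scan %s x %s: %s", drug, code, exc)
                results.append(SignalResult(drug, level, code, name, None, False, error=str(exc)))
                continue
            results.append(
                SignalResult(drug, level, code, name, stats, detect_signal(stats, min_count))
            )

    def sort_key(r: SignalResult):
        if level == "pt":
            hlt_code = d.pts[r.code].hlt_code
            return (r.drug, d.hlts[hlt_code].hlt_name, r.name, r.code)
        return (r.drug, r.name, r.code)

    results.sort(key=sort_key)
    return results


def results_to_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Tabulate scan results with full-precision and display-rounded
    (2-decimal, half-up) columns."""
    rows = []
    for r in results:
        s = r.stats
        rows.append(
            {
                "drug": r.drug,
                "level": r.level,
                "code": r.code,
                "name": r.name,
                "n": None if s is None else s.n_reports,
                "ror": None if s is None else s.ror,
                "ci_low": None if s is None else s.ci_low,
                "ci_high": None if s is None else s.ci_high,
                "ror_2dp": None if s is None else round_half_up(s.ror),
                "ci_low_2dp": None if s is None else round_half_up(s.ci_low),
                "ci_high_2dp": None if s is None else round_half_up(s.ci_high),
                "corrected": None if s is None else s.corrected,
                "positive": r.positive,
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows)
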