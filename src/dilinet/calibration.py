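"""Simulation calibration experiments for the signal-detection chain.

Two standing experiments validate the whole generator -> deduplication ->
contingency -> ROR chain:

- **Null calibration**: with every planted odds multiplier at 1, the
  positive-signal rule (n >= 3 reports and CI lower bound > 1) should fire
  for a fixed monitored pair in roughly the nominal one-sided 2.5% of
  replicate databases; the count criterion adds slack, so the rate is
  asserted against a loose 7% bound.
- **Recovery**: with omega = 4 planted on the monitored pair, the 95% CI
  should cover 4.0 in at least 90% of replicates and the median ROR
  estimate should sit near 4.

The replicate database is deliberately minimal — two drugs, one monitored
event plus the background filler — because the estimand of a 2x2 scan
involves exactly one drug margin and one event margin. Each replicate gets
an independent seed derived from one master seed via numpy's SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disproportionality import build_contingency, compute_ror, detect_signal
from .reports import deduplicate
from .synthetic import SimulationConfig, simulate_database

MONITORED_DRUG = "drugA"
MONITORED_PT = "PT_EVENT"


def replicate_config(n_cases: int, omega: float, seed: int) -> SimulationConfig:
    """One calibration replicate: two drugs, one monitored event, omega
    planted on (drugA, PT_EVENT); 10% duplicate case versions keep the
    deduplication step on the tested path."""
    planted = {(MONITORED_DRUG, MONITORED_PT): omega} if omega != 1.0 else {}
    return SimulationConfig(
        n_cases=n_cases,
        drugs=[(MONITORED_DRUG, 0.15), ("drugB", 0.50)],
        events=[(MONITORED_PT, 0.05)],
        planted_or=planted,
        duplicate_fraction=0.10,
        multi_drug_probability=0.05,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    n_replicates: int
    coverage: float        # fraction of replicate CIs containing the true OR
    median_ror: float
    positive_rate: float   # fraction of replicates flagged positive
    rors: list[float]


def _replicate_stats(n_cases: int, omega: float, seed: int):
    frame, _ = simulate_database(replicate_config(n_cases, omega, seed))
    clean = deduplicate(frame)
    table = build_contingency(clean, MONITORED_DRUG, {MONITORED_PT})
    return compute_ror(table)


def run_replicates(
    n_replicates: int, n_cases: int, omega: float, seed: int
) -> RecoveryResult:
    """Simulate independent databases and summarize the monitored pair."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rors, covered, positive = [], 0, 0
    for s in child_seeds:
        stats = _replicate_stats(n_cases, omega, int(s))
        rors.append(stats.ror)
        if stats.ci_low <= omega <= stats.ci_high:
            covered += 1
        if detect_signal(stats):
            positive += 1
    return RecoveryResult(
        n_replicates=n_replicates,
        coverage=covered / n_replicates,
        median_ror=float(np.median(rors)),
        positive_rate=positive / n_replicates,
        rors=rors,
    )


def null_signal_rate(n_replicates: int = 500, n_cases: int = 2000, seed: int = 0) -> float:
    """Fraction of all-null replicate databases where the monitored pair
    is (falsely) flagged positive."""
    return run_replicates(n_replicates, n_cases, omega=1.0, seed=seed).positive_rate


def planted_recovery(
    n_replicates: int = 200, n_cases: int = 5000, omega: float = 4.0, seed: int = 0
) -> RecoveryResult:
    """CI coverage and ROR distribution with ``omega`` planted."""
    return run_replicates(n_replicates, n_cases, omega=omega, seed=seed)
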