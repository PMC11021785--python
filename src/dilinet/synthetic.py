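"""Synthetic spontaneous-report databases with planted disproportionality.

The generator emulates the structure of a FAERS-style extraction: one row
per report-drug-event assertion, duplicate case versions, missing
demographics and onset dates, and — crucially — a known ground truth. Event
occurrence follows a logistic-odds model: each event's odds for a case are
its baseline odds multiplied by the planted odds multiplier omega of every
exposed drug carrying one. The reporting odds ratio is therefore the
estimand: a pair with planted omega has asymptotic ROR equal to omega, and
omega = 1 everywhere yields a null database.

Every case yields at least one event row: cases drawing no event receive a
background filler PT (spontaneous reports always carry at least one coded
event). Without this the no-event cases would silently vanish from the
table and bias the ROR away from the planted value.

All draws come from a single seeded numpy Generator in a fixed vectorised
order (each quantity drawn for all cases before masks apply), so identical
config + seed gives byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._common import ConfigError
from .reports import REPORT_COLUMNS

STUDY_START = np.datetime64("2014-01-01")
THERAPY_START_WINDOW_DAYS = 3257  # therapy starts up to 2022-12-01
STUDY_END = np.datetime64("2023-03-31")

#: Fixed categorical menus (probabilities chosen to resemble a breast-cancer
#: pharmacovigilance cohort: overwhelmingly female, mostly 50-70 years old,
#: reported by health professionals slightly more often than consumers).
SEX_MENU = (("F", 0.90), ("M", 0.10))
REPORTER_MENU = (("consumer", 0.42), ("health_professional", 0.53), ("unknown", 0.05))
OUTCOME_MENU = (
    ("Life-Threatening", 0.04),
    ("Hospitalization", 0.27),
    ("Disability", 0.01),
    ("Death", 0.16),
    ("Other", 0.32),
    ("", 0.20),  # missing
)


def _check_fraction(name: str, value: float, closed_top: bool = False) -> None:
    hi_ok = value <= 1.0 if closed_top else value < 1.0
    if not (0.0 <= value and hi_ok):
        top = "1]" if closed_top else "1)"
        raise ConfigError(f"{name}: must be in [0,{top}, got {value}")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic database.

    ``drugs`` is a list of (name, exposure_probability); ``events`` of
    (pt_code, baseline_event_probability); ``planted_or`` maps
    (drug, pt_code) to an odds multiplier omega > 0 (pairs not listed have
    omega = 1). ``onset_median_days`` is a single median or a per-drug map;
    onset intervals are log-normal around it.
    """

    n_cases: int
    drugs: list[tuple[str, float]]
    events: list[tuple[str, float]]
    planted_or: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_fraction: float = 0.0
    multi_drug_probability: float = 0.0
    concomitant_probability: float = 0.10
    missing_age_fraction: float = 0.15
    missing_sex_fraction: float = 0.05
    missing_onset_fraction: float = 0.50
    onset_median_days: float | dict[str, float] = 30.0
    onset_log_sigma: float = 1.0
    background_pt: str = "PT_BACKGROUND"
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_cases, int) or self.n_cases < 1:
            raise ConfigError(f"n_cases: must be a positive integer, got {self.n_cases!r}")
        if not self.drugs:
            raise ConfigError("drugs: at least one drug is required")
        if not self.events:
            raise ConfigError("events: at least one event is required")
        names = [d for d, _ in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigError("drugs: duplicate drug names")
        codes = [e for e, _ in self.events]
        if len(set(codes)) != len(codes):
            raise ConfigError("events: duplicate pt_codes")
        if self.background_pt in codes:
            raise ConfigError("background_pt: must not collide with an event pt_code")
        for d, p in self.drugs:
            if not 0.0 < p < 1.0:
                raise ConfigError(f"drugs[{d}]: exposure_probability must be in (0,1), got {p}")
        for e, p in self.events:
            if not 0.0 < p < 1.0:
                raise ConfigError(f"events[{e}]: baseline_event_probability must be in (0,1), got {p}")
        for (d, e), omega in self.planted_or.items():
            if d not in names:
                raise ConfigError(f"planted_or[{d},{e}]: unknown drug {d!r}")
            if e not in codes:
                raise ConfigError(f"planted_or[{d},{e}]: unknown pt_code {e!r}")
            if not omega > 0:
                raise ConfigError(f"planted_or[{d},{e}]: omega must be > 0, got {omega}")
        _check_fraction("duplicate_fraction", self.duplicate_fraction)
        _check_fraction("multi_drug_probability", self.multi_drug_probability)
        _check_fraction("concomitant_probability", self.concomitant_probability)
        _check_fraction("missing_age_fraction", self.missing_age_fraction)
        _check_fraction("missing_sex_fraction", self.missing_sex_fraction)
        _check_fraction("missing_onset_fraction", self.missing_onset_fraction)
        medians = (
            self.onset_median_days.values()
            if isinstance(self.onset_median_days, dict)
            else [self.onset_median_days]
        )
        for m in medians:
            if not m > 0:
                raise ConfigError(f"onset_median_days: must be positive, got {m}")
        if self.onset_log_sigma <= 0:
            raise ConfigError(f"onset_log_sigma: must be positive, got {self.onset_log_sigma}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed: must be an integer, got {self.seed!r}")

    def median_for(self, drug: str) -> float:
        if isinstance(self.onset_median_days, dict):
            return float(self.onset_median_days.get(drug, 30.0))
        return float(self.onset_median_days)

    def to_json_dict(self) -> dict:
        planted: dict[str, dict[str, float]] = {}
        for (d, e), omega in self.planted_or.items():
            planted.setdefault(d, {})[e] = omega
        return {
            "n_cases": self.n_cases,
            "drugs": [{"name": d, "exposure_probability": p} for d, p in self.drugs],
            "events": [{"pt_code": e, "baseline_event_probability": p} for e, p in self.events],
            "planted_or": planted,
            "duplicate_fraction": self.duplicate_fraction,
            "multi_drug_probability": self.multi_drug_probability,
            "concomitant_probability": self.concomitant_probability,
            "missing_age_fraction": self.missing_age_fraction,
            "missing_sex_fraction": self.missing_sex_fraction,
            "missing_onset_fraction": self.missing_onset_fraction,
            "onset_median_days": self.onset_median_days,
            "onset_log_sigma": self.onset_log_sigma,
            "background_pt": self.background_pt,
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "SimulationConfig":
        try:
            planted = {
                (d, e): float(omega)
                for d, inner in data.get("planted_or", {}).items()
                for e, omega in inner.items()
            }
            return cls(
                n_cases=data["n_cases"],
                drugs=[(d["name"], float(d["exposure_probability"])) for d in data["drugs"]],
                events=[
                    (e["pt_code"], float(e["baseline_event_probability"])) for e in data["events"]
                ],
                planted_or=planted,
                duplicate_fraction=float(data.get("duplicate_fraction", 0.0)),
                multi_drug_probability=float(data.get("multi_drug_probability", 0.0)),
                concomitant_probability=float(data.get("concomitant_probability", 0.10)),
                missing_age_fraction=float(data.get("missing_age_fraction", 0.15)),
                missing_sex_fraction=float(data.get("missing_sex_fraction", 0.05)),
                missing_onset_fraction=float(data.get("missing_onset_fraction", 0.50)),
                onset_median_days=data.get("onset_median_days", 30.0),
                onset_log_sigma=float(data.get("onset_log_sigma", 1.0)),
                background_pt=data.get("background_pt", "PT_BACKGROUND"),
                seed=int(data.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config field: {exc.args[0]}") from None

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class GroundTruth:
    """Latent state of one simulated database."""

    planted_or: dict[tuple[str, str], float]
    exposures: dict[str, list[str]]     # case_id -> exposed (suspect) drugs
    case_events: dict[str, list[str]]   # case_id -> event PTs (incl. filler)
    duplicates: dict[str, list[str]]    # case_id -> all report_ids (>= 2)

    def to_json_dict(self) -> dict:
        return {
            "planted_or": {f"{d}|{e}": w for (d, e), w in sorted(self.planted_or.items())},
            "exposures": self.exposures,
            "case_events": self.case_events,
            "duplicates": self.duplicates,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _categorical(u: np.ndarray, menu) -> np.ndarray:
    labels = [m[0] for m in menu]
    probs = np.array([m[1] for m in menu])
    cuts = np.cumsum(probs) / probs.sum()
    idx = np.searchsorted(cuts, u, side="right").clip(max=len(labels) - 1)
    return np.array(labels, dtype=object)[idx]


def simulate_database(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one report table plus its ground truth.

    Exposure to each drug is an independent Bernoulli draw at its exposure
    probability; cases drawing no drug are assigned one (probability
    proportional to the exposure probabilities), and an extra suspect drug
    is added with ``multi_drug_probability`` — exercising multi-suspect
    cases. Exposed drugs are recorded with role PS; with
    ``concomitant_probability`` one non-suspect drug is added with role C
    (it carries no planted effect, so role filtering matters downstream).
    ``duplicate_fraction`` of cases are re-emitted as a follow-up version
    with an incremented version number and later receipt date.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drug_names = [d for d, _ in config.drugs]
    p_drug = np.array([p for _, p in config.drugs])
    event_codes = [e for e, _ in config.events]
    p_event = np.array([p for _, p in config.events])
    n_drugs, n_events = len(drug_names), len(event_codes)

    # -- latent structure (fixed draw order) -------------------------------
    exposure = rng.random((n, n_drugs)) < p_drug
    forced = rng.choice(n_drugs, size=n, p=p_drug / p_drug.sum())
    none = ~exposure.any(axis=1)
    exposure[none, forced[none]] = True
    extra_flag = rng.random(n) < config.multi_drug_probability
    extra_pick = rng.integers(0, n_drugs, size=n)
    exposure[extra_flag, extra_pick[extra_flag]] = True

    log_odds = np.tile(np.log(p_event / (1 - p_event)), (n, 1))
    for (drug, code), omega in config.planted_or.items():
        i, j = drug_names.index(drug), event_codes.index(code)
        log_odds[:, j] += exposure[:, i] * math.log(omega)
    p_case = 1.0 / (1.0 + np.exp(-log_odds))
    events = rng.random((n, n_events)) < p_case

    conc_flag = rng.random(n) < config.concomitant_probability
    conc_pick = rng.integers(0, n_drugs, size=n)

    # -- demographics, outcomes, dates (fixed draw order) ------------------
    sex = _categorical(rng.random(n), SEX_MENU)
    sex[rng.random(n) < config.missing_sex_fraction] = ""
    age = np.round(np.clip(rng.normal(62.0, 12.0, size=n), 18.0, 95.0)).astype(int)
    age_missing = rng.random(n) < config.missing_age_fraction
    reporter = _categorical(rng.random(n), REPORTER_MENU)
    outcome = _categorical(rng.random(n), OUTCOME_MENU)

    start_offset = rng.integers(0, THERAPY_START_WINDOW_DAYS, size=n)
    onset_z = rng.normal(0.0, 1.0, size=n)
    primary = exposure.argmax(axis=1)
    medians = np.array([config.median_for(drug_names[i]) for i in primary])
    onset_days = np.round(
        np.exp(np.log(medians) + config.onset_log_sigma * onset_z)
    ).astype(int)
    onset_missing = rng.random(n) < config.missing_onset_fraction
    report_delay = np.round(rng.exponential(30.0, size=n)).astype(int)

    n_dup = int(math.floor(config.duplicate_fraction * n))
    dup_idx = set(rng.choice(n, size=n_dup, replace=False).tolist()) if n_dup else set()
    dup_gap = rng.integers(10, 200, size=n)

    therapy_start = STUDY_START + start_offset
    event_onset = therapy_start + onset_days
    receipt = np.minimum(event_onset + report_delay, STUDY_END)

    # -- emit rows ---------------------------------------------------------
    rows: list[tuple] = []
    exposures: dict[str, list[str]] = {}
    case_events: dict[str, list[str]] = {}
    duplicates: dict[str, list[str]] = {}
    for i in range(n):
        case_id = f"C{i + 1:06d}"
        exp_drugs = [drug_names[j] for j in np.flatnonzero(exposure[i])]
        evts = [event_codes[j] for j in np.flatnonzero(events[i])]
        if not evts:
            evts = [config.background_pt]
        exposures[case_id] = exp_drugs
        case_events[case_id] = evts

        drug_roles = [(d, "PS") for d in exp_drugs]
        conc = drug_names[conc_pick[i]]
        if conc_flag[i] and conc not in exp_drugs:
            drug_roles.append((conc, "C"))

        start_s = "" if onset_missing[i] else str(therapy_start[i])
        onset_s = "" if onset_missing[i] else str(event_onset[i])
        age_s = "" if age_missing[i] else int(age[i])

        versions = [(1, receipt[i])]
        if i in dup_idx:
            versions.append((2, np.minimum(receipt[i] + dup_gap[i], STUDY_END)))
        report_ids = []
        for version, rcpt in versions:
            report_id = f"{case_id}-{version}"
            report_ids.append(report_id)
            year = int(str(rcpt)[:4])
            for drug, role in drug_roles:
                for evt in evts:
                    rows.append(
                        (
                            report_id, case_id, version, str(rcpt), drug, role, evt,
                            sex[i], age_s, year, reporter[i], outcome[i],
                            start_s, onset_s,
                        )
                    )
        if len(report_ids) > 1:
            duplicates[case_id] = report_ids

    frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    truth = GroundTruth(
        planted_or=dict(config.planted_or),
        exposures=exposures,
        case_events=case_events,
        duplicates=duplicates,
    )
    return frame, truth


def write_reports_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report table byte-stably (LF line endings, no index)."""
    frame.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Fixture bundle: a small self-consistent file set exercising every reader.
# ---------------------------------------------------------------------------

_FIXTURE_HLTS = [
    ("HLT001", "Liver function analyses"),
    ("HLT002", "Hepatic failure and associated disorders"),
    ("HLT003", "Cholestasis and jaundice"),
    ("HLT004", "Hepatocellular damage and hepatitis NEC"),
    ("HLT005", "Gastrointestinal signs and symptoms"),
    ("HLT006", "Haematological disorders NEC"),
    ("HLT007", "General disorders NEC"),
]

_FIXTURE_PTS = [
    ("PT_ALT_INC", "Alanine aminotransferase increased", "HLT001"),
    ("PT_AST_INC", "Aspartate aminotransferase increased", "HLT001"),
    ("PT_BILI_INC", "Blood bilirubin increased", "HLT001"),
    ("PT_LFT_ABN", "Liver function test abnormal", "HLT001"),
    ("PT_HEP_FAIL", "Hepatic failure", "HLT002"),
    ("PT_CIRRHOSIS", "Hepatic cirrhosis", "HLT002"),
    ("PT_JAUNDICE", "Jaundice", "HLT003"),
    ("PT_HEPATITIS", "Hepatitis", "HLT004"),
    ("PT_HEPATOTOX", "Hepatotoxicity", "HLT004"),
    ("PT_NAUSEA", "Nausea", "HLT005"),
    ("PT_DIARRHOEA", "Diarrhoea", "HLT005"),
    ("PT_NEUTROPENIA", "Neutropenia", "HLT006"),
    ("PT_FATIGUE", "Fatigue", "HLT007"),
    ("PT_OTHER", "Adverse event NOS", "HLT007"),
]

# Two child SMQs under one comprehensive liver-injury query; PT_JAUNDICE is
# a member of both children (SMQ membership is many-to-many) and
# PT_BILI_INC/PT_HEPATITIS carry broad scope.
_FIXTURE_SMQS = [
    ("SMQ_LIV_INV", "Liver related investigations, signs and symptoms", "PT_ALT_INC", "narrow"),
    ("SMQ_LIV_INV", "Liver related investigations, signs and symptoms", "PT_AST_INC", "narrow"),
    ("SMQ_LIV_INV", "Liver related investigations, signs and symptoms", "PT_BILI_INC", "broad"),
    ("SMQ_LIV_INV", "Liver related investigations, signs and symptoms", "PT_LFT_ABN", "narrow"),
    ("SMQ_LIV_INV", "Liver related investigations, signs and symptoms", "PT_JAUNDICE", "broad"),
    ("SMQ_LIV_DAMAGE", "Hepatic failure, fibrosis and other liver damage", "PT_HEP_FAIL", "narrow"),
    ("SMQ_LIV_DAMAGE", "Hepatic failure, fibrosis and other liver damage", "PT_CIRRHOSIS", "narrow"),
    ("SMQ_LIV_DAMAGE", "Hepatic failure, fibrosis and other liver damage", "PT_JAUNDICE", "narrow"),
    ("SMQ_LIV_DAMAGE", "Hepatic failure, fibrosis and other liver damage", "PT_HEPATITIS", "broad"),
    ("SMQ_LIV_DAMAGE", "Hepatic failure, fibrosis and other liver damage", "PT_HEPATOTOX", "narrow"),
]

_FIXTURE_SMQ_CHILDREN = [
    ("SMQ_LIV_COMP", "SMQ_LIV_INV"),
    ("SMQ_LIV_COMP", "SMQ_LIV_DAMAGE"),
]

_FIXTURE_TARGET_GENES = [
    "CDK4", "CDK6", "CCND1", "RB1", "STAT3", "HSP90AA1", "EP300", "HIF1A",
    "ESR1", "PIK3CA", "NFKB1", "STAT1", "PIK3R1", "CREBBP", "SIRT1", "PPARG",
    "AKT1", "MTOR", "EGFR", "ERBB2", "AURKA", "PLK1", "WEE1", "CHEK1",
    "GSK3B", "MAPK1", "SRC", "ABL1",
]

_FIXTURE_DISEASE_GENES = [
    "STAT3", "HSP90AA1", "EP300", "HIF1A", "NFKB1", "STAT1", "SIRT1", "PPARG",
    "PIK3CA", "AKT1", "MTOR", "CREBBP", "TNF", "IL6", "TP53", "ALB", "CYP2E1",
    "CYP3A4", "ABCB11", "SLCO1B1", "NR1H4", "HMOX1", "NFE2L2", "CASP3",
    "BAX", "BCL2", "TGFB1", "COL1A1", "ACTA2", "ADIPOQ", "LEP", "SOD2",
    "GPX1", "CAT", "UGT1A1",
]

# STRING-style scores on the 0-1000 integer scale; several fall below the
# 0.7 threshold and several touch genes outside the intersection.
_FIXTURE_EDGES = [
    ("STAT3", "STAT1", 998), ("STAT3", "EP300", 962), ("STAT3", "HIF1A", 945),
    ("STAT3", "NFKB1", 951), ("STAT3", "SIRT1", 902), ("STAT3", "AKT1", 930),
    ("STAT3", "MTOR", 880), ("EP300", "CREBBP", 999), ("EP300", "HIF1A", 988),
    ("EP300", "NFKB1", 940), ("EP300", "SIRT1", 915), ("EP300", "STAT1", 905),
    ("HSP90AA1", "STAT3", 921), ("HSP90AA1", "HIF1A", 933), ("HSP90AA1", "AKT1", 961),
    ("HSP90AA1", "MTOR", 870), ("HIF1A", "SIRT1", 844), ("HIF1A", "CREBBP", 957),
    ("NFKB1", "STAT1", 872), ("NFKB1", "SIRT1", 861), ("PIK3CA", "AKT1", 992),
    ("PIK3CA", "MTOR", 903), ("AKT1", "MTOR", 995), ("PPARG", "EP300", 896),
    ("PPARG", "SIRT1", 912), ("PPARG", "NFKB1", 688), ("CREBBP", "STAT1", 690),
    ("SIRT1", "AKT1", 655), ("HSP90AA1", "EP300", 602), ("PIK3CA", "STAT3", 578),
    ("MTOR", "PPARG", 430), ("TP53", "EP300", 991), ("TNF", "NFKB1", 996),
    ("IL6", "STAT3", 993), ("CDK4", "CCND1", 999), ("CDK6", "CCND1", 997),
]

_FIXTURE_GMT = [
    ("hsa04151", "PI3K-Akt signaling pathway",
     ["PIK3CA", "PIK3R1", "AKT1", "MTOR", "NFKB1", "HSP90AA1", "CCND1", "TP53", "IL6"]),
    ("hsa04630", "JAK-STAT signaling pathway",
     ["STAT3", "STAT1", "PIK3CA", "AKT1", "EP300", "CREBBP", "CCND1", "IL6"]),
    ("hsa04110", "Cell cycle",
     ["CDK4", "CDK6", "CCND1", "RB1", "EP300", "CREBBP", "TP53", "CHEK1", "WEE1", "PLK1"]),
    ("hsa04066", "HIF-1 signaling pathway",
     ["HIF1A", "EP300", "CREBBP", "STAT3", "AKT1", "MTOR", "PIK3CA", "HMOX1"]),
    ("hsa04068", "FoxO signaling pathway",
     ["AKT1", "PIK3CA", "PIK3R1", "SIRT1", "STAT3", "EP300", "CCND1", "MAPK1"]),
    ("hsa05200", "Pathways in cancer",
     ["STAT3", "STAT1", "HIF1A", "NFKB1", "PIK3CA", "AKT1", "MTOR", "EGFR",
      "ERBB2", "CCND1", "CDK4", "CDK6", "RB1", "TP53", "BAX", "BCL2"]),
    ("hsa04931", "Insulin resistance",
     ["PPARG", "SIRT1", "AKT1", "NFKB1", "MTOR", "ADIPOQ", "LEP", "GSK3B"]),
]

_FIXTURE_SYNONYMS = [
    ("IBRANCE", "palbociclib"),
    ("KISQALI", "ribociclib"),
    ("VERZENIO", "abemaciclib"),
    ("palbociclib hydrochloride", "palbociclib"),
    ("ribociclib succinate", "ribociclib"),
]


def fixture_simulation_config(seed: int) -> SimulationConfig:
    """The simulation settings of the standard fixture bundle: three study
    drugs against three comparators, liver and non-liver events, and four
    planted pairs of known effect size."""
    return SimulationConfig(
        n_cases=800,
        drugs=[
            ("palbociclib", 0.12),
            ("ribociclib", 0.10),
            ("abemaciclib", 0.08),
            ("letrozole", 0.25),
            ("fulvestrant", 0.20),
            ("anastrozole", 0.18),
        ],
        events=[
            ("PT_ALT_INC", 0.030),
            ("PT_AST_INC", 0.030),
            ("PT_BILI_INC", 0.020),
            ("PT_LFT_ABN", 0.020),
            ("PT_HEP_FAIL", 0.010),
            ("PT_CIRRHOSIS", 0.005),
            ("PT_JAUNDICE", 0.010),
            ("PT_HEPATITIS", 0.010),
            ("PT_HEPATOTOX", 0.008),
            ("PT_NAUSEA", 0.150),
            ("PT_DIARRHOEA", 0.100),
            ("PT_NEUTROPENIA", 0.080),
            ("PT_FATIGUE", 0.150),
        ],
        planted_or={
            ("ribociclib", "PT_ALT_INC"): 3.5,
            ("ribociclib", "PT_AST_INC"): 3.5,
            ("abemaciclib", "PT_HEP_FAIL"): 4.0,
            ("palbociclib", "PT_NEUTROPENIA"): 2.0,
        },
        duplicate_fraction=0.12,
        multi_drug_probability=0.04,
        concomitant_probability=0.15,
        missing_age_fraction=0.20,
        missing_sex_fraction=0.06,
        missing_onset_fraction=0.55,
        onset_median_days={"palbociclib": 48.0, "abemaciclib": 32.0, "ribociclib": 42.0},
        onset_log_sigma=1.0,
        background_pt="PT_OTHER",
        seed=seed,
    )


def _write_csv(path: Path, header: list[str], rows) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def make_fixture_bundle(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write a self-consistent small bundle of every input the pipeline
    reads; returns a name -> path map. Deterministic in ``seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dict_dir = out / "dict"
    dict_dir.mkdir(exist_ok=True)
    _write_csv(dict_dir / "hlt.csv", ["hlt_code", "hlt_name"], _FIXTURE_HLTS)
    _write_csv(dict_dir / "pt.csv", ["pt_code", "pt_name", "hlt_code"], _FIXTURE_PTS)
    _write_csv(dict_dir / "smq.csv", ["smq_code", "smq_name", "pt_code", "scope"], _FIXTURE_SMQS)
    _write_csv(dict_dir / "smq_children.csv", ["parent_code", "child_code"], _FIXTURE_SMQ_CHILDREN)

    config = fixture_simulation_config(seed)
    frame, truth = simulate_database(config)
    write_reports_csv(frame, out / "reports.csv")
    truth.write_json(out / "truth.json")
    with open(out / "sim_config.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    (out / "targets.txt").write_text("\n".join(_FIXTURE_TARGET_GENES) + "\n", encoding="utf-8")
    (out / "disease_genes.txt").write_text(
        "\n".join(_FIXTURE_DISEASE_GENES) + "\n", encoding="utf-8"
    )
    with open(out / "string_edges.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in _FIXTURE_EDGES:
            fh.write(f"{a}\t{b}\t{s}\n")
    with open(out / "pathways.gmt", "w", encoding="utf-8", newline="\n") as fh:
        for pid, name, members in _FIXTURE_GMT:
            fh.write("\t".join([pid, name, *members]) + "\n")
    _write_csv(out / "synonyms.csv", ["alias", "canonical"], _FIXTURE_SYNONYMS)

    return {
        "reports": out / "reports.csv",
        "truth": out / "truth.json",
        "sim_config": out / "sim_config.json",
        "dict_dir": dict_dir,
        "targets": out / "targets.txt",
        "disease_genes": out / "disease_genes.txt",
        "edges": out / "string_edges.tsv",
        "gmt": out / "pathways.gmt",
        "synonyms": out / "synonyms.csv",
    }
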