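"""ROR estimation, Woolf intervals, the signal rule and hierarchy scans."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilinet import (
    ContingencyTable,
    DegenerateMarginError,
    SignalStats,
    build_contingency,
    compute_ror,
    deduplicate,
    detect_signal,
    expand_query,
    scan_signals,
)
from dilinet.disproportionality import results_to_frame
from dilinet.reports import ReportRecord


def record(report_id, case_id, drug, pt, role="PS"):
    return ReportRecord(
        report_id=report_id, case_id=case_id, case_version=1, receipt_date="2020-01-01",
        drug_name=drug, drug_role=role, pt_code=pt, sex="F", age_years=None,
        report_year=2020, reporter="consumer", outcome="",
        therapy_start_date="", event_onset_date="",
    )


class TestContingency:
    def test_exhaustive_four_report_toy(self):
        records = [
            record("R1", "C1", "drugA", "PT_E"),
            record("R2", "C2", "drugA", "PT_X"),
            record("R3", "C3", "drugB", "PT_E"),
            record("R4", "C4", "drugB", "PT_X"),
        ]
        t = build_contingency(deduplicate(records), "drugA", {"PT_E"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_any_match_counts_report_once_across_member_pts(self):
        records = [
            record("R1", "C1", "drugA", "PT_E1"),
            record("R1", "C1", "drugA", "PT_E2"),
            record("R2", "C2", "drugB", "PT_X"),
        ]
        t = build_contingency(deduplicate(records), "drugA", {"PT_E1", "PT_E2"})
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_fixture_table_matches_brute_force_enumeration(self, clean, synonyms, meddra_dict):
        pt_set = expand_query(meddra_dict, "smq", "SMQ_LIV_COMP")
        t = build_contingency(clean, "ribociclib", pt_set, synonyms)
        # independent oracle: per-report flags recomputed row by row
        flags = {}
        for r in clean.records:
            has_drug, has_event = flags.get(r.report_id, (False, False))
            if r.drug_role == "PS" and r.drug_name.strip().casefold().startswith("ribociclib"):
                has_drug = True
            if r.pt_code in pt_set:
                has_event = True
            flags[r.report_id] = (has_drug, has_event)
        a = sum(1 for hd, he in flags.values() if hd and he)
        b = sum(1 for hd, he in flags.values() if hd and not he)
        c = sum(1 for hd, he in flags.values() if not hd and he)
        d = sum(1 for hd, he in flags.values() if not hd and not he)
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        assert t.total == clean.n_reports

    def test_all_pt_query_forces_empty_b_margin(self, clean, synonyms, meddra_dict):
        all_pts = set(meddra_dict.pts)
        t = build_contingency(clean, "ribociclib", all_pts, synonyms)
        assert t.b == 0  # every report carries at least one PT

    def test_empty_pt_set_rejected(self, clean):
        with pytest.raises(ValueError, match="pt_set"):
            build_contingency(clean, "ribociclib", set())

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            ContingencyTable(1, -1, 1, 1)


class TestComputeRor:
    def test_symmetric_table_is_null(self):
        s = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert s.ror == pytest.approx(1.0)
        assert s.ci_low < 1.0 < s.ci_high

    def test_frozen_example_against_extended_precision_oracle(self):
        # oracle: closed form recomputed with exact rationals
        a, b, c, d = 5, 95, 100, 9900
        oracle_ror = Fraction(a * d, b * c)
        oracle_se = math.sqrt(
            float(Fraction(1, a) + Fraction(1, b) + Fraction(1, c) + Fraction(1, d))
        )
        s = compute_ror(ContingencyTable(a, b, c, d))
        assert s.ror == pytest.approx(float(oracle_ror), abs=1e-12)
        assert s.se_log == pytest.approx(oracle_se, abs=1e-12)
        assert s.ror == pytest.approx(5.2105, abs=5e-5)
        assert s.se_log == pytest.approx(0.46971, abs=5e-6)
        assert s.ci_low == pytest.approx(2.0752, abs=5e-5)
        assert s.ci_high == pytest.approx(13.0830, abs=5e-4)

    def test_single_zero_cell_triggers_correction_but_raw_count_kept(self):
        s = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert s.corrected
        assert s.n_reports == 0
        assert s.ror > 0

    def test_degenerate_margins_raise(self):
        with pytest.raises(DegenerateMarginError):
            compute_ror(ContingencyTable(0, 0, 5, 5))
        with pytest.raises(DegenerateMarginError):
            compute_ror(ContingencyTable(5, 5, 0, 0))

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, cells):
        a, b, c, d = cells
        s = compute_ror(ContingencyTable(a, b, c, d))
        r = compute_ror(ContingencyTable(b, a, d, c))
        assert r.ror == pytest.approx(1 / s.ror, rel=1e-12)
        assert r.ci_low == pytest.approx(1 / s.ci_high, rel=1e-12)
        assert r.ci_high == pytest.approx(1 / s.ci_low, rel=1e-12)

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_woolf_geometry_point_estimate_is_geometric_mean(self, cells):
        s = compute_ror(ContingencyTable(*cells))
        assert math.exp((math.log(s.ci_low) + math.log(s.ci_high)) / 2) == pytest.approx(
            s.ror, rel=1e-12
        )

    def test_equals_brute_force_odds_ratio_on_small_grid(self):
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            s = compute_ror(ContingencyTable(a, b, c, d))
            assert s.ror == pytest.approx(float(Fraction(a * d, b * c)), rel=1e-12)

    def test_ci_coverage_at_true_or_two(self):
        # multinomial cell probabilities with odds ratio exactly 2
        probs = np.array([2.0, 1.0, 1.0, 1.0])
        probs = probs / probs.sum()
        rng = np.random.default_rng(2024)
        covered = 0
        n_rep = 1000
        for counts in rng.multinomial(400, probs, size=n_rep):
            s = compute_ror(ContingencyTable(*(int(x) for x in counts)))
            covered += s.ci_low <= 2.0 <= s.ci_high
        assert 0.93 <= covered / n_rep <= 0.97


class TestDetectSignal:
    @pytest.mark.parametrize(
        "n, ci_low, expected",
        [
            (3, 1.05, True),     # boundary count included
            (2, 8.0, False),     # strong ROR but too few reports
            (10, 1.0, False),    # bound must be strictly above 1
            (2256, 0.67, False),  # large negative-signal cohort
        ],
    )
    def test_rule(self, n, ci_low, expected):
        s = SignalStats(ror=2.0, ci_low=ci_low, ci_high=9.0, se_log=0.5,
                        n_reports=n, corrected=False)
        assert detect_signal(s) is expected


class TestScan:
    def test_planted_pairs_only_positive_at_pt_level(self, clean, synonyms, meddra_dict):
        results = scan_signals(
            clean, ["ribociclib"], meddra_dict, "pt", None, "combined", 3, synonyms
        )
        positives = {r.code for r in results if r.positive}
        assert positives == {"PT_ALT_INC", "PT_AST_INC"}  # the planted pairs
        assert any(not r.positive for r in results)  # negatives retained

    def test_smq_scan_equals_union_pt_set(self, clean, synonyms, meddra_dict):
        [res] = scan_signals(
            clean, ["ribociclib"], meddra_dict, "smq", ["SMQ_LIV_COMP"], "combined", 3, synonyms
        )
        pt_set = expand_query(meddra_dict, "smq", "SMQ_LIV_COMP")
        direct = compute_ror(build_contingency(clean, "ribociclib", pt_set, synonyms))
        assert res.stats == direct

    def test_pt_results_sorted_by_hlt_then_pt_name(self, clean, synonyms, meddra_dict):
        results = scan_signals(
            clean, ["ribociclib"], meddra_dict, "pt", None, "combined", 3, synonyms
        )
        keys = [
            (meddra_dict.hlts[meddra_dict.pts[r.code].hlt_code].hlt_name, r.name)
            for r in results
        ]
        assert keys == sorted(keys)

    def test_degenerate_pair_reported_not_raised(self, meddra_dict, synonyms):
        records = [record("R1", "C1", "drugA", "PT_ALT_INC")]
        results = scan_signals(
            deduplicate(records), ["drugA"], meddra_dict, "pt", ["PT_ALT_INC"]
        )
        assert results[0].stats is None and results[0].error

    def test_results_frame_has_display_rounding(self, clean, synonyms, meddra_dict):
        results = scan_signals(
            clean, ["ribociclib"], meddra_dict, "smq", ["SMQ_LIV_COMP"], "combined", 3, synonyms
        )
        df = results_to_frame(results)
        row = df.iloc[0]
        assert row["ror_2dp"] == pytest.approx(round(row["ror"], 2), abs=0.005 + 1e-12)
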