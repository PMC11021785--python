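"""Report reading, case deduplication and primary-suspect filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilinet import (
    SchemaError,
    deduplicate,
    filter_primary_suspect,
    multi_drug_cases,
    read_reports,
    read_reports_detailed,
)
from dilinet.reports import REPORT_COLUMNS, records_to_frame

HEADER = ",".join(REPORT_COLUMNS)


def make_row(
    report_id="R1",
    case_id="C1",
    case_version=1,
    receipt_date="2020-01-01",
    drug_name="ribociclib",
    drug_role="PS",
    pt_code="PT001",
    sex="F",
    age_years="60",
    report_year=2020,
    reporter="consumer",
    outcome="Hospitalization",
    therapy_start_date="",
    event_onset_date="",
):
    return ",".join(
        str(v)
        for v in (
            report_id, case_id, case_version, receipt_date, drug_name, drug_role,
            pt_code, sex, age_years, report_year, reporter, outcome,
            therapy_start_date, event_onset_date,
        )
    )


def write_table(tmp_path, rows, name="reports.csv"):
    path = tmp_path / name
    path.write_text(HEADER + "\n" + "\n".join(rows) + ("\n" if rows else ""), encoding="utf-8")
    return path


class TestRead:
    def test_fixture_record_count_equals_data_rows(self, bundle):
        with open(bundle["reports"], encoding="utf-8") as fh:
            n_rows = sum(1 for _ in fh) - 1
        assert len(read_reports(bundle["reports"])) == n_rows

    def test_version_zero_rejected_and_counted(self, tmp_path):
        path = write_table(tmp_path, [make_row(), make_row(report_id="R2", case_version=0)])
        records, issues = read_reports_detailed(path, max_bad_fraction=0.9)
        assert len(records) == 1
        assert len(issues) == 1 and issues[0].line == 3
        assert "case_version" in issues[0].reason

    def test_empty_file_with_header_is_empty_list(self, tmp_path):
        assert read_reports(write_table(tmp_path, [])) == []

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("report_id,case_id\nR1,C1\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="drug_name"):
            read_reports(path)

    def test_too_many_bad_rows_aborts(self, tmp_path):
        rows = [make_row()] + [make_row(report_id=f"R{i}", drug_role="XX") for i in range(9)]
        with pytest.raises(Exception, match="invalid"):
            read_reports(write_table(tmp_path, rows), max_bad_fraction=0.5)

    def test_negative_onset_interval_rejected(self, tmp_path):
        bad = make_row(therapy_start_date="2020-05-01", event_onset_date="2020-04-01")
        _, issues = read_reports_detailed(write_table(tmp_path, [bad]), max_bad_fraction=1.0)
        assert len(issues) == 1


class TestDeduplicate:
    def test_highest_version_survives(self, tmp_path):
        rows = [
            make_row(report_id="R1", case_version=1, pt_code="PT001"),
            make_row(report_id="R2", case_version=2, pt_code="PT001"),
            make_row(report_id="R3", case_version=3, pt_code="PT001"),
            make_row(report_id="R3", case_version=3, pt_code="PT002"),
        ]
        clean = deduplicate(read_reports(write_table(tmp_path, rows)))
        assert set(clean.frame.report_id) == {"R3"}
        assert clean.counters["rows_dedup_dropped"] == 2

    def test_distinct_cases_both_retained(self, tmp_path):
        rows = [make_row(), make_row(report_id="R2", case_id="C2")]
        clean = deduplicate(read_reports(write_table(tmp_path, rows)))
        assert clean.n_reports == 2

    def test_tie_breaks_receipt_then_report_id(self, tmp_path):
        rows = [
            make_row(report_id="RA", case_version=2, receipt_date="2020-01-01"),
            make_row(report_id="RB", case_version=2, receipt_date="2020-06-01"),
            make_row(report_id="RC", case_version=1, receipt_date="2021-01-01"),
        ]
        clean = deduplicate(read_reports(write_table(tmp_path, rows)))
        assert set(clean.frame.report_id) == {"RB"}

    def test_ten_cases_three_duplicated_enumeration(self, tmp_path):
        # 10 cases; C1, C2, C3 duplicated once each -> 13 report versions.
        rows, superseded = [], 0
        for i in range(1, 11):
            rows.append(make_row(report_id=f"R{i}v1", case_id=f"C{i}", case_version=1))
            if i <= 3:
                rows.append(make_row(report_id=f"R{i}v2", case_id=f"C{i}", case_version=2))
                superseded += 1
        clean = deduplicate(read_reports(write_table(tmp_path, rows)))
        assert clean.n_reports == 10
        assert clean.counters["rows_dedup_dropped"] == superseded == 3
        assert clean.counters["rows_read"] == 13

    def test_repeated_triples_collapse_within_report(self, tmp_path):
        rows = [make_row(pt_code="PT001"), make_row(pt_code="PT001")]
        clean = deduplicate(read_reports(write_table(tmp_path, rows)))
        assert clean.counters["rows_collapsed"] == 1
        assert len(clean.frame) == 1


@st.composite
def report_tables(draw):
    n = draw(st.integers(1, 25))
    rows = []
    for i in range(n):
        rows.append(
            dict(
                report_id=f"R{i}",
                case_id=f"C{draw(st.integers(1, 6))}",
                case_version=draw(st.integers(1, 4)),
                receipt_date=draw(st.sampled_from(["", "2020-01-01", "2021-06-15"])),
                drug_name=draw(st.sampled_from(["drugA", "drugB", "DrugA "])),
                drug_role=draw(st.sampled_from(["PS", "SS", "C"])),
                pt_code=draw(st.sampled_from(["PT1", "PT2", "PT3"])),
            )
        )
    return rows


class TestDedupProperties:
    @given(report_tables())
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_conserving(self, rows):
        records = read_rows(rows)
        once = deduplicate(records)
        twice = deduplicate(once.frame.drop(columns="drug_norm"))
        assert once.frame.drop(columns="drug_norm").reset_index(drop=True).equals(
            twice.frame.drop(columns="drug_norm").reset_index(drop=True)
        )
        assert twice.counters["rows_dedup_dropped"] == 0
        c = once.counters
        assert c["rows_read"] == c["rows_retained"] + c["rows_dedup_dropped"] + c["rows_collapsed"]
        # per-case uniqueness afterwards
        assert (once.frame.groupby("case_id")["report_id"].nunique() == 1).all()

    @given(report_tables())
    @settings(max_examples=60, deadline=None)
    def test_dedup_never_increases_pair_counts(self, rows):
        records = read_rows(rows)
        before = records_to_frame(records)
        after = deduplicate(records).frame
        for (drug, pt), grp in after.groupby(["drug_name", "pt_code"]):
            n_before = len(
                before[(before.drug_name == drug) & (before.pt_code == pt)]["report_id"].unique()
            )
            assert grp["report_id"].nunique() <= n_before


def read_rows(rows):
    from dilinet import ReportRecord

    return [
        ReportRecord(
            report_id=r["report_id"],
            case_id=r["case_id"],
            case_version=r["case_version"],
            receipt_date=r["receipt_date"],
            drug_name=r["drug_name"],
            drug_role=r["drug_role"],
            pt_code=r["pt_code"],
            sex="F",
            age_years=None,
            report_year=2020,
            reporter="consumer",
            outcome="",
            therapy_start_date="",
            event_onset_date="",
        )
        for r in rows
    ]


class TestPrimarySuspectFilter:
    def test_only_ps_rows_kept(self, tmp_path):
        rows = [
            make_row(report_id="R1", drug_role="PS"),
            make_row(report_id="R2", drug_role="SS"),
            make_row(report_id="R3", drug_role="C"),
        ]
        records = read_reports(write_table(tmp_path, rows))
        kept = filter_primary_suspect(records, "ribociclib")
        assert [r.report_id for r in kept] == ["R1"]

    def test_case_and_whitespace_normalization(self, tmp_path):
        rows = [
            make_row(report_id="R1", drug_name="Ribociclib "),
            make_row(report_id="R2", drug_name="RIBOCICLIB"),
            make_row(report_id="R3", drug_name="ribociclib succinate"),
        ]
        records = read_reports(write_table(tmp_path, rows))
        assert len(filter_primary_suspect(records, "ribociclib")) == 3

    def test_brand_name_synonyms(self, tmp_path, synonyms):
        rows = [
            make_row(report_id="R1", drug_name="KISQALI"),
            make_row(report_id="R2", drug_name="kisqali"),
            make_row(report_id="R3", drug_name="letrozole"),
        ]
        records = read_reports(write_table(tmp_path, rows))
        assert len(filter_primary_suspect(records, "ribociclib", synonyms)) == 2
        assert len(filter_primary_suspect(records, "ribociclib")) == 0

    def test_empty_drug_rejected(self):
        with pytest.raises(ValueError, match="drug"):
            filter_primary_suspect([], "  ")


def test_multi_drug_case_diagnostic(tmp_path):
    rows = [
        make_row(report_id="R1", case_id="C1", drug_name="ribociclib"),
        make_row(report_id="R1", case_id="C1", drug_name="palbociclib"),
        make_row(report_id="R2", case_id="C2", drug_name="ribociclib"),
    ]
    clean = deduplicate(read_reports(write_table(tmp_path, rows)))
    found = multi_drug_cases(clean, ["ribociclib", "palbociclib", "abemaciclib"])
    assert found == {"C1": ["palbociclib", "ribociclib"]}
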