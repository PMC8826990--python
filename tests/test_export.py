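"""CSV/JSON exports, PHI masking safety, and the study summary report."""

import csv
import io
import json

import pytest

from ecrfkit import (
    EdcError,
    ExportOptions,
    FixtureSpec,
    Study,
    export_csv,
    export_json,
    generate_study_config,
    simulate_entry,
    study_summary,
    summarize_study,
    summary_csv,
    table3_fixture,
)
from conftest import GOOD_PAYLOAD, TickingClock, make_config


@pytest.fixture
def populated(config, clock):
    study = Study(config, b"s", clock=clock)
    study.register_participant("S01", "P1")
    study.register_participant("S02", "P2")
    study.submit_record("P1", "BL", "DEMOG",
                        {**GOOD_PAYLOAD, "SSN": "123-45-6789"}, "u")
    study.submit_record(
        "P2", "BL", "DEMOG",
        {"SEX": "2", "AGE": "61", "PREGNANT": "2", "VISIT_DATE": "2021-02-03",
         "SSN": "999-88-7777"},
        "u",
    )
    # P2 leaves WEIGHT explicitly missing via an edit
    rec = study.find_record("P2", "BL", "DEMOG")
    study.edit_record(rec.record_doi, {}, "u", rfc="mark missing", missing={"WEIGHT"})
    return study


def parse_csv(text):
    return list(csv.reader(io.StringIO(text)))


class TestCsvExport:
    def test_key_block_then_fields_in_order(self, populated):
        rows = parse_csv(export_csv(populated, "DEMOG"))
        assert rows[0][:7] == ["study_id", "site_id", "participant_id", "event_code",
                               "instance_no", "version", "revision"]
        assert rows[0][7:] == ["SEX", "AGE", "PREGNANT", "PREG_WEEKS", "VISIT_DATE",
                               "ONSET", "WAKE", "WEIGHT", "NOTES", "SSN"]

    def test_row_per_live_instance(self, populated):
        rows = parse_csv(export_csv(populated, "DEMOG"))
        assert len(rows) - 1 == 2
        rec = populated.find_record("P1", "BL", "DEMOG")
        populated.delete_record(rec.record_doi, "u", rfc="entered in error")
        rows = parse_csv(export_csv(populated, "DEMOG"))
        assert len(rows) - 1 == 1

    def test_phi_masked_by_default_in_every_cell(self, populated):
        rows = parse_csv(export_csv(populated, "DEMOG"))
        ssn_idx = rows[0].index("SSN")
        assert all(row[ssn_idx] == "[MASKED]" for row in rows[1:])

    def test_phi_drop_removes_column(self, populated):
        rows = parse_csv(export_csv(populated, "DEMOG", ExportOptions(phi_mode="drop")))
        assert "SSN" not in rows[0]

    def test_phi_include_requires_explicit_override(self, populated):
        with pytest.raises(EdcError) as exc:
            ExportOptions(phi_mode="include")
        assert exc.value.code == "PHI_OVERRIDE_REQUIRED"
        rows = parse_csv(
            export_csv(populated, "DEMOG",
                       ExportOptions(phi_mode="include", confirm_include_phi=True))
        )
        ssn_idx = rows[0].index("SSN")
        assert "123-45-6789" in [row[ssn_idx] for row in rows[1:]]

    def test_missing_token_distinct_from_unanswered(self, populated):
        rows = parse_csv(export_csv(populated, "DEMOG"))
        header = rows[0]
        by_pid = {row[header.index("participant_id")]: row for row in rows[1:]}
        weight = header.index("WEIGHT")
        notes = header.index("NOTES")
        assert by_pid["P2"][weight] == "MISSING"   # checked missing
        assert by_pid["P2"][notes] == ""           # simply unanswered
        assert by_pid["P1"][weight] == "72.5"

    def test_unknown_crf(self, populated):
        with pytest.raises(EdcError) as exc:
            export_csv(populated, "GHOST")
        assert exc.value.code == "UNKNOWN_CRF"

    def test_export_is_deterministic_byte_identical(self, populated):
        assert export_csv(populated, "DEMOG") == export_csv(populated, "DEMOG")
        a = json.dumps(export_json(populated), sort_keys=True)
        b = json.dumps(export_json(populated), sort_keys=True)
        assert a == b


class TestJsonExport:
    def test_empty_study_is_valid_document(self, config):
        study = Study(config, b"s")
        doc = export_json(study)
        assert doc["participants"] == []

    def test_nesting_and_item_statuses(self, populated):
        doc = export_json(populated)
        p2 = next(p for p in doc["participants"] if p["participant_id"] == "P2")
        rec = p2["events"][0]["records"][0]
        items = rec["items"]
        assert items["WEIGHT"]["status"] == "missing"
        assert items["PREGNANT"]["status"] == "answered"  # visible for SEX=2
        assert items["PREG_WEEKS"]["status"] == "hidden"  # PREGNANT=2
        assert items["SSN"]["value"] == "[MASKED]"

    def test_audit_history_lengths_match_ledger(self, populated):
        rec = populated.find_record("P1", "BL", "DEMOG")
        populated.edit_record(rec.record_doi, {"AGE": "43"}, "u", rfc="fix")
        doc = export_json(populated, ExportOptions(include_audit=True))
        p1 = next(p for p in doc["participants"] if p["participant_id"] == "P1")
        json_rec = p1["events"][0]["records"][0]
        assert json_rec["record_history_length"] == \
            populated.ledger.history(rec.record_doi).version_count == 2
        assert len(json_rec["items"]["AGE"]["history"]) == \
            populated.ledger.history(rec.item_dois["AGE"]).version_count == 2

    def test_csv_json_value_multisets_agree_for_non_phi(self, populated):
        options = ExportOptions()
        rows = parse_csv(export_csv(populated, "DEMOG", options))
        header = rows[0]
        csv_pairs = set()
        for row in rows[1:]:
            for name in header[7:]:
                if name == "SSN":
                    continue
                value = row[header.index(name)]
                if value:
                    csv_pairs.add((row[2], row[3], "DEMOG", name, value))
        json_pairs = set()
        for p in export_json(populated, options)["participants"]:
            for ev in p["events"]:
                for rec in ev["records"]:
                    for name, item in rec["items"].items():
                        if name == "SSN" or item["value"] is None:
                            continue
                        json_pairs.add((p["participant_id"], ev["event_code"],
                                        rec["crf_name"], name, item["value"]))
        assert csv_pairs == json_pairs

    def test_no_phi_raw_value_substring_anywhere(self, populated):
        phi_raw = {"123-45-6789", "999-88-7777"}
        blobs = [export_csv(populated, "DEMOG"),
                 json.dumps(export_json(populated)),
                 export_csv(populated, "DEMOG", ExportOptions(phi_mode="drop")),
                 json.dumps(export_json(populated, ExportOptions(phi_mode="drop",
                                                                 include_audit=True)))]
        for blob in blobs:
            for raw in phi_raw:
                assert raw not in blob


class TestStudySummary:
    def test_totals_row_matches_published_table(self):
        rows, totals = study_summary(table3_fixture())
        assert len(rows) == 7
        assert totals.n_participants_screened == 4596
        assert totals.n_ecrfs == 337816
        assert totals.n_queries == 36887
        assert totals.n_transactions == 381868
        assert totals.n_image_studies == 703
        assert totals.query_rate_pct is None  # blank in the totals row

    def test_live_study_counts_match_brute_force_scan(self, populated):
        populated.docs.create_topic("docs")
        populated.docs.upload_file("docs", "f.txt", b"1", "u")
        populated.docs.upload_file("docs", "f.txt", b"2", "u")
        summary = summarize_study(populated)
        ledger = populated.ledger
        assert summary.n_ecrfs == sum(
            1 for r in populated.records.values() if r.state == "active"
        )
        assert summary.n_transactions == sum(
            1 for e in ledger.entries if e.object_type == "form-record"
        )
        assert summary.n_transactions >= summary.n_ecrfs
        assert summary.n_queries == len(populated.queries.queries)
        assert (summary.n_files, summary.n_file_versions) == (1, 2)
        assert summary.n_participants_screened == 2

    def test_empty_study_all_zero_blank_rate(self, config):
        rows, totals = study_summary([Study(config, b"s")])
        assert rows[0].n_ecrfs == 0 and rows[0].query_rate_pct is None

    def test_summary_csv_blank_rate_cell_in_totals(self):
        rows, totals = study_summary(table3_fixture())
        text = summary_csv(rows, totals)
        last = text.strip().splitlines()[-1].split(",")
        assert last[0] == "Total"
        rate_idx = text.splitlines()[0].split(",").index("query_rate_pct")
        assert last[rate_idx] == ""
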