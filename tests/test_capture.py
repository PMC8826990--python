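"""Record capture, event matrix, locks, prospective revisioning, workflows."""

from datetime import timedelta

import pytest

from ecrfkit import (
    CRFDefinition,
    CRFVersion,
    DuplicateError,
    EdcError,
    FieldDefinition,
    LockedError,
    NotFoundError,
    Study,
    WorkflowDefinition,
    WorkflowStep,
)
from conftest import (
    GOOD_PAYLOAD,
    T0,
    TickingClock,
    demo_fields,
    make_config,
    make_revision,
    mls,
)


class TestParticipants:
    def test_register_initializes_all_required_missing(self, study):
        study.register_participant("S01", "P1")
        matrix = study.compute_event_matrix("P1")
        assert {c.status for c in matrix.cells.values()} == {"missing"}
        assert set(matrix.cells) == {("BL", "DEMOG"), ("M06", "DEMOG")}

    def test_duplicate_id_rejected(self, study):
        study.register_participant("S01", "P1")
        with pytest.raises(DuplicateError):
            study.register_participant("S02", "P1")

    def test_unknown_site_rejected(self, study):
        with pytest.raises(EdcError) as exc:
            study.register_participant("S99", "P1")
        assert exc.value.code == "UNKNOWN_SITE"


class TestSubmit:
    def test_valid_payload_complete_no_queries(self, study):
        study.register_participant("S01", "P1")
        rec, findings, opened = study.submit_record("P1", "BL", "DEMOG",
                                                    GOOD_PAYLOAD, "site-user")
        assert findings == [] and opened == []
        assert rec.is_complete

    def test_error_finding_stores_raw_and_opens_one_query(self, study):
        study.register_participant("S01", "P1")
        rec, findings, opened = study.submit_record(
            "P1", "BL", "DEMOG", {**GOOD_PAYLOAD, "AGE": "150"}, "site-user"
        )
        assert [f.rule_id for f in findings] == ["RANGE"]
        assert rec.payload.values["AGE"] == "150"  # raw value stored
        assert len(opened) == 1
        assert opened[0].origin == "auto" and opened[0].rule_id == "RANGE"

    def test_second_instance_forbidden_without_multiple_entry(self, study):
        study.register_participant("S01", "P1")
        study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        with pytest.raises(EdcError) as exc:
            study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        assert exc.value.code == "MULTIPLE_ENTRY_FORBIDDEN"

    def test_unknown_event_and_crf(self, study):
        study.register_participant("S01", "P1")
        with pytest.raises(EdcError) as exc:
            study.submit_record("P1", "XX", "DEMOG", GOOD_PAYLOAD, "u")
        assert exc.value.code == "UNKNOWN_EVENT"
        with pytest.raises(EdcError) as exc:
            study.submit_record("P1", "BL", "NOPE", GOOD_PAYLOAD, "u")
        assert exc.value.code == "UNKNOWN_CRF"


class TestEdit:
    def test_correction_system_closes_auto_query(self, study):
        study.register_participant("S01", "P1")
        rec, _, opened = study.submit_record(
            "P1", "BL", "DEMOG", {**GOOD_PAYLOAD, "AGE": "150"}, "u"
        )
        before = study.n_record_transactions()
        _, findings, closed = study.edit_record(rec.record_doi, {"AGE": "48"}, "u",
                                                rfc="transcription error")
        assert findings == []
        assert [q.query_id for q in closed] == [opened[0].query_id]
        q = study.queries.get(opened[0].query_id)
        assert q.status == "closed"
        assert q.conversation[-1].actor == "system"
        assert study.n_record_transactions() == before + 1

    def test_edit_requires_rfc_and_unlocked(self, study):
        study.register_participant("S01", "P1")
        rec, _, _ = study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        with pytest.raises(EdcError):
            study.edit_record(rec.record_doi, {"AGE": "43"}, "u", rfc="")
        study.lock(("record", rec.record_doi), "monitor")
        with pytest.raises(LockedError):
            study.edit_record(rec.record_doi, {"AGE": "43"}, "u", rfc="r")

    def test_enclosing_scope_lock_blocks_edit_and_submit(self, study):
        study.register_participant("S01", "P1")
        rec, _, _ = study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        study.lock(study.event_scope("P1", "BL"), "monitor")
        with pytest.raises(LockedError):
            study.edit_record(rec.record_doi, {"AGE": "43"}, "u", rfc="r")
        with pytest.raises(LockedError):
            study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        # the other event is unaffected
        study.submit_record("P1", "M06", "DEMOG", GOOD_PAYLOAD, "u")


class TestEventMatrix:
    def test_complete_with_queries_and_event_counts(self, study):
        study.register_participant("S01", "P1")
        rec, _, _ = study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        study.queries.open_query(rec.record_doi, "dm", "please confirm age",
                                 field_name="AGE")
        m = study.compute_event_matrix("P1")
        assert m.cells[("BL", "DEMOG")].status == "complete-with-queries"
        assert m.event_open_queries == {"BL": 1, "M06": 0}

    def test_progress_counts_required_visible_fields(self, study):
        study.register_participant("S01", "P1")
        # 5 required visible for SEX=1 (SEX, AGE, VISIT_DATE, WEIGHT + hidden
        # PREGNANT not counted); answer 3 of them
        payload = {"SEX": "1", "AGE": "42", "VISIT_DATE": "2021-01-01"}
        study.submit_record("P1", "BL", "DEMOG", payload, "u")
        cell = study.compute_event_matrix("P1").cells[("BL", "DEMOG")]
        assert cell.status == "incomplete"
        assert cell.progress == (3, 4)

    def test_locked_status(self, study):
        study.register_participant("S01", "P1")
        rec, _, _ = study.submit_record("P1", "BL", "DEMOG", GOOD_PAYLOAD, "u")
        study.lock(("record", rec.record_doi), "monitor")
        m = study.compute_event_matrix("P1")
        assert m.cells[("BL", "DEMOG")].status == "locked"

    def test_replay_reproduces_matrix_exactly(self, study):
        study.register_participant("S01", "P1")
        rec, _, _ = study.submit_record(
            "P1", "BL", "DEMOG", {**GOOD_PAYLOAD, "AGE": "150"}, "u"
        )
        study.edit_record(rec.record_doi, {"AGE": "50"}, "u", rfc="fix")
        study.sdv(("record", rec.record_doi), "monitor")
        replayed = Study.replay(study.config, study.ledger)
        assert replayed.compute_event_matrix("P1") == study.compute_event_matrix("P1")
        assert replayed.n_record_transactions() == study.n_record_transactions()


class TestProspectiveRevisioning:
    def test_new_required_field_applies_only_to_new_records(self):
        r1 = make_revision(revision_no=1, activated_at=T0)
        new_field = FieldDefinition("EDUC", mls("Education years"), 11, "input", "N",
                                    required=True)
        r2 = make_revision(tuple(demo_fields()) + (new_field,), revision_no=2,
                           activated_at=T0 + timedelta(hours=1))
        config = make_config(revisions=(r1, r2))
        clock = TickingClock()  # starts seconds after T0, before revision 2
        study = Study(config, b"s", clock=clock)
        study.register_participant("S01", "P1")
        rec_old, findings, _ = study.submit_record("P1", "BL", "DEMOG",
                                                   GOOD_PAYLOAD, "u")
        assert rec_old.revision_no == 1 and findings == []
        clock.now = T0 + timedelta(hours=2)
        rec_new, findings, _ = study.submit_record("P1", "M06", "DEMOG",
                                                   GOOD_PAYLOAD, "u")
        assert rec_new.revision_no == 2
        assert [f.field_name for f in findings if f.rule_id == "REQUIRED"] == ["EDUC"]
        # editing the old record still validates under revision 1
        _, findings, _ = study.edit_record(rec_old.record_doi, {"AGE": "43"}, "u",
                                           rfc="r")
        assert findings == []


class TestCrossEvents:
    def _study(self):
        meds = CRFDefinition(
            crf_name="CONMED", crf_label="Concomitant medications",
            versions=(CRFVersion("v1", (make_revision(),)),),
            allow_multiple_entry=True, is_cross_events=True,
        )
        config = make_config(extra_crfs=(meds,))
        study = Study(config, b"s", clock=TickingClock())
        study.register_participant("S01", "P1")
        return study

    def test_cross_event_records_visible_from_every_event(self):
        study = self._study()
        rec, _, _ = study.submit_record("P1", "BL", "CONMED", GOOD_PAYLOAD, "u")
        m = study.compute_event_matrix("P1")
        assert rec.record_doi in m.supplemental["BL"]
        assert rec.record_doi in m.supplemental["M06"]

    def test_cross_event_instances_share_one_sequence(self):
        study = self._study()
        r1, _, _ = study.submit_record("P1", "BL", "CONMED", GOOD_PAYLOAD, "u")
        r2, _, _ = study.submit_record("P1", "M06", "CONMED", GOOD_PAYLOAD, "u")
        assert (r1.instance_no, r2.instance_no) == (1, 2)
        assert r2.event_code == "M06"  # originating event retained


class TestWorkflows:
    def test_insert_then_edit_applies_both_steps(self, study):
        study.register_participant("S01", "P1")
        wf = WorkflowDefinition(
            name="enter-and-correct",
            steps=(
                WorkflowStep("insert", {"participant": "$pid", "event": "BL",
                                        "crf": "DEMOG", "values": GOOD_PAYLOAD}),
                WorkflowStep("edit", {"values": {"AGE": "43"}, "rfc": "correction"}),
            ),
        )
        study.register_workflow(wf)
        before = study.n_record_transactions()
        run = study.run_workflow("enter-and-correct", {"pid": "P1"}, "u")
        assert [o["outcome"] for o in run.outcomes] == ["applied", "applied"]
        assert study.n_record_transactions() == before + 2

    def test_false_condition_skips_without_ledger_write(self, study):
        study.register_participant("S01", "P1")
        wf = WorkflowDefinition(
            name="conditional",
            steps=(
                WorkflowStep("insert", {"participant": "$pid", "event": "BL",
                                        "crf": "DEMOG", "values": GOOD_PAYLOAD},
                             condition="mode = batch"),
            ),
        )
        study.register_workflow(wf)
        before = study.n_record_transactions()
        run = study.run_workflow("conditional", {"pid": "P1", "mode": "manual"}, "u")
        assert run.outcomes[0]["outcome"] == "skipped"
        assert study.n_record_transactions() == before
        run = study.run_workflow("conditional", {"pid": "P1", "mode": "batch"}, "u")
        assert run.outcomes[0]["outcome"] == "applied"

    def test_unregistered_handler_rejected_at_registration(self, study):
        wf = WorkflowDefinition(
            name="bad", steps=(WorkflowStep("execute", handler="ghost"),)
        )
        with pytest.raises(EdcError) as exc:
            study.register_workflow(wf)
        assert exc.value.code == "HANDLER_UNKNOWN"

    def test_failed_step_halts_run(self, study):
        wf = WorkflowDefinition(
            name="fails",
            steps=(
                WorkflowStep("insert", {"participant": "GHOST", "event": "BL",
                                        "crf": "DEMOG", "values": {}}),
                WorkflowStep("annotate", {"text": "never reached"}),
            ),
        )
        study.register_workflow(wf)
        run = study.run_workflow("fails", {}, "u")
        assert [o["outcome"] for o in run.outcomes] == ["failed"]

    def test_execute_and_copy_actions(self, study):
        study.register_participant("S01", "P1")
        seen = []
        study.register_handler("notify-team", lambda s, ctx: seen.append(ctx["pid"]) or "ok")
        wf = WorkflowDefinition(
            name="copy-forward",
            steps=(
                WorkflowStep("insert", {"participant": "$pid", "event": "BL",
                                        "crf": "DEMOG", "values": GOOD_PAYLOAD}),
                WorkflowStep("copy", {"event": "M06"}),
                WorkflowStep("execute", handler="notify-team"),
            ),
        )
        study.register_workflow(wf)
        run = study.run_workflow("copy-forward", {"pid": "P1"}, "u")
        assert [o["outcome"] for o in run.outcomes] == ["applied"] * 3
        assert seen == ["P1"]
        m = study.compute_event_matrix("P1")
        assert m.cells[("M06", "DEMOG")].status == "complete"


class TestConfigGate:
    def test_config_with_error_findings_refused_by_capture(self):
        fields = list(demo_fields())
        fields.append(fields[0])  # duplicate field name
        config = make_config(revisions=(make_revision(fields),))
        with pytest.raises(EdcError) as exc:
            Study(config, b"s")
        assert exc.value.code == "CONFIG_INVALID"
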