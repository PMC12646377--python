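"""Parsing FHIR R4 streams into typed records and writing RiskAssessment."""

from __future__ import annotations

import datetime as dt
import http.server
import json
import threading

import pytest

from fhirpipe import (
    RiskAssessmentRecord,
    SUPPORTED_RESOURCE_TYPES,
    Sex,
    Task,
    merge_encounters,
    parse_resources,
    parse_riskassessment,
    push_resources,
    write_riskassessment,
)
from fhirpipe.fhir_io import ConfigurationError, extract_events
from fhirpipe.types import EncounterRecord, Insurance

from conftest import ts


def _bundle(*resources):
    return json.dumps({"resourceType": "Bundle",
                       "entry": [{"resource": r} for r in resources]})


def _ndjson(*resources):
    return "\n".join(json.dumps(r) for r in resources)


PATIENT = {"resourceType": "Patient", "id": "p1", "gender": "female",
           "birthDate": "1980-06-15"}
ENCOUNTER = {"resourceType": "Encounter", "id": "e1",
             "subject": {"reference": "Patient/p1"},
             "period": {"start": "2021-03-01T08:00:00Z",
                        "end": "2021-03-05T12:00:00Z"},
             "class": {"code": "IMP"}}
OBSERVATION = {"resourceType": "Observation", "id": "o1",
               "subject": {"reference": "Patient/p1"},
               "encounter": {"reference": "Encounter/e1"},
               "effectiveDateTime": "2021-03-02T09:30:00Z",
               "code": {"coding": [{"system": "http://loinc.org",
                                    "code": "2345-7", "display": "Glucose"}]},
               "valueQuantity": {"value": 6.1, "unit": "mmol/L"}}


class TestParseResources:
    def test_minimal_patient_field_mapping(self):
        result = parse_resources(_ndjson(PATIENT))
        assert len(result.patients) == 1
        patient = result.patients[0]
        assert patient.patient_id == "p1"
        assert patient.sex is Sex.FEMALE
        assert patient.birth_date == dt.date(1980, 6, 15)
        assert result.skipped == 0

    def test_unsupported_resource_counted_not_fatal(self):
        bundle = _bundle(PATIENT, {"resourceType": "AllergyIntolerance",
                                   "id": "a1"})
        result = parse_resources(bundle)
        assert result.events == []
        assert result.skipped == 1

    def test_observation_value_quantity(self):
        result = parse_resources(_bundle(OBSERVATION))
        (event,) = result.events
        assert event.resource_type == "Observation"
        assert event.patient_id == "p1"
        assert event.encounter_id == "e1"
        assert event.timestamp == ts(2021, 3, 2, 9, 30)
        assert event.code.code == "2345-7"
        assert event.value_quantity == (6.1, "mmol/L")

    def test_bundle_and_ndjson_dialects_agree(self):
        resources = [PATIENT, ENCOUNTER, OBSERVATION]
        a = parse_resources(_bundle(*resources))
        b = parse_resources(_ndjson(*resources))
        assert [p.patient_id for p in a.patients] == [p.patient_id for p in b.patients]
        assert [e.event_id for e in a.events] == [e.event_id for e in b.events]

    def test_concatenation_is_union(self):
        a = _ndjson(PATIENT, OBSERVATION)
        b = _ndjson(ENCOUNTER)
        joint = parse_resources(a + "\n" + b)
        separate_ids = {e.event_id for e in parse_resources(a).events} | {
            e.event_id for e in parse_resources(b).events}
        assert {e.event_id for e in joint.events} == separate_ids
        assert len(joint.encounters) == 1

    def test_missing_id_skipped(self):
        result = parse_resources(_ndjson({"resourceType": "Patient",
                                          "gender": "male"}))
        assert result.patients == []
        assert result.skipped == 1

    def test_missing_timestamp_skipped(self):
        cond = {"resourceType": "Condition", "id": "c1",
                "subject": {"reference": "Patient/p1"},
                "code": {"coding": [{"code": "I10.0"}]}}
        result = parse_resources(_ndjson(cond))
        assert result.events == []
        assert result.skipped == 1

    def test_timezone_normalized_to_utc(self):
        obs = dict(OBSERVATION, effectiveDateTime="2021-03-02T11:30:00+02:00")
        (event,) = parse_resources(_ndjson(obs)).events
        assert event.timestamp == ts(2021, 3, 2, 9, 30)

    def test_date_only_is_midnight_utc(self):
        cond = {"resourceType": "Condition", "id": "c1",
                "subject": {"reference": "Patient/p1"},
                "recordedDate": "2021-03-02",
                "code": {"coding": [{"code": "I10.0"}]}}
        (event,) = parse_resources(_ndjson(cond)).events
        assert event.timestamp == ts(2021, 3, 2, 0, 0)

    def test_coverage_maps_insurance(self):
        coverage = {"resourceType": "Coverage", "id": "cov1",
                    "beneficiary": {"reference": "Patient/p1"},
                    "type": {"coding": [{"code": "PKV"}]}}
        result = parse_resources(_ndjson(PATIENT, coverage))
        assert result.patients[0].insurance is Insurance.PRIVATE
        assert result.skipped == 0

    def test_supported_type_set_has_ten_members(self, small_parsed):
        assert len(set(SUPPORTED_RESOURCE_TYPES)) == 10
        assert {e.resource_type for e in small_parsed.events} <= set(
            SUPPORTED_RESOURCE_TYPES)


class TestExtractEvents:
    def test_diagnostic_report_conclusion(self):
        report = {"resourceType": "DiagnosticReport", "id": "d1",
                  "subject": {"reference": "Patient/p1"},
                  "effectiveDateTime": "2021-03-02T10:00:00Z",
                  "conclusion": "No acute findings."}
        (event,) = extract_events(_ndjson(report), "DiagnosticReport")
        assert event.value_text == "No acute findings."

    def test_procedure_period_fallback(self):
        proc = {"resourceType": "Procedure", "id": "pr1",
                "subject": {"reference": "Patient/p1"},
                "performedPeriod": {"start": "2021-03-03T14:00:00Z",
                                    "end": "2021-03-03T15:00:00Z"},
                "code": {"coding": [{"code": "1-632"}]}}
        (event,) = extract_events(_ndjson(proc), "Procedure")
        assert event.timestamp == ts(2021, 3, 3, 14)

    def test_imaging_study_modality_set(self):
        study = {"resourceType": "ImagingStudy", "id": "im1",
                 "subject": {"reference": "Patient/p1"},
                 "started": "2021-03-01T09:00:00Z",
                 "series": [{"modality": {"code": "CT"}},
                            {"modality": {"code": "CT"}}]}
        events = extract_events(_ndjson(study), "ImagingStudy")
        assert len(events) == 1
        assert {c.code for c in events[0].codes} == {"CT"}

    def test_medication_family_normalized(self):
        med = {"resourceType": "MedicationRequest", "id": "m1",
               "subject": {"reference": "Patient/p1"},
               "authoredOn": "2021-03-02T08:00:00Z",
               "medicationCodeableConcept": {"coding": [{"code": "C03CA01"}]}}
        (event,) = extract_events(_ndjson(med), "MedicationStatement")
        assert event.resource_type == "Medication"

    def test_sorted_by_timestamp(self, small_population):
        events = extract_events(small_population.to_ndjson(), "Observation")
        stamps = [e.timestamp for e in events]
        assert stamps == sorted(stamps)

    def test_unknown_type_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            extract_events("", "CarePlan")


class TestMergeEncounters:
    def test_overlapping_stays_collapse(self):
        a = EncounterRecord("a", "p1", ts(2021, 3, 1), ts(2021, 3, 5))
        b = EncounterRecord("b", "p1", ts(2021, 3, 4), ts(2021, 3, 9))
        (merged,) = merge_encounters([a, b])
        assert merged.start == ts(2021, 3, 1)
        assert merged.end == ts(2021, 3, 9)
        assert set(merged.merged_ids) == {"a", "b"}

    def test_disjoint_stays_preserved(self):
        a = EncounterRecord("a", "p1", ts(2021, 3, 1), ts(2021, 3, 5))
        b = EncounterRecord("b", "p1", ts(2021, 4, 1), ts(2021, 4, 3))
        assert len(merge_encounters([a, b])) == 2

    def test_death_flag_survives_merge(self):
        a = EncounterRecord("a", "p1", ts(2021, 3, 1), ts(2021, 3, 5),
                            died_in_encounter=True)
        b = EncounterRecord("b", "p1", ts(2021, 3, 5), ts(2021, 3, 9))
        (merged,) = merge_encounters([a, b])
        assert merged.died_in_encounter


class TestRiskAssessment:
    def _record(self, probability=0.5):
        return RiskAssessmentRecord(
            subject="p1", task=Task.READMISSION, probability=probability,
            outcome_code="positive", occurrence=ts(2021, 5, 1, 12),
            model_version="m-1", encounter="e1", assessment_id="ra1",
        )

    def test_probability_rendered(self):
        resource = write_riskassessment(self._record(0.5))
        assert resource["resourceType"] == "RiskAssessment"
        assert resource["status"] == "final"
        assert resource["subject"]["reference"] == "Patient/p1"
        assert resource["prediction"][0]["probabilityDecimal"] == 0.5

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            self._record(1.2)

    def test_round_trip_identity(self):
        record = self._record(0.73)
        assert parse_riskassessment(write_riskassessment(record)) == record


class _MockHandler(http.server.BaseHTTPRequestHandler):
    fail_ids: set = set()

    def _respond(self):
        body = self.rfile.read(int(self.headers.get("Content-Length", 0)))
        rid = json.loads(body).get("id")
        code = 500 if rid in self.fail_ids else 201
        self.send_response(code)
        self.send_header("Content-Length", "0")
        self.end_headers()

    do_POST = _respond
    do_PUT = _respond

    def log_message(self, *args):
        pass


@pytest.fixture()
def mock_server():
    server = http.server.HTTPServer(("127.0.0.1", 0), _MockHandler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    yield f"http://127.0.0.1:{server.server_port}/fhir"
    server.shutdown()


class TestPushResources:
    def test_empty_list(self, mock_server):
        assert push_resources([], mock_server) == []

    def test_all_created(self, mock_server):
        _MockHandler.fail_ids = set()
        resources = [{"resourceType": "RiskAssessment", "id": f"r{i}"}
                     for i in range(3)]
        statuses = push_resources(resources, mock_server)
        assert all(s.ok and s.status_code == 201 for s in statuses)

    def test_single_failure_recorded(self, mock_server):
        _MockHandler.fail_ids = {"r1"}
        resources = [{"resourceType": "RiskAssessment", "id": f"r{i}"}
                     for i in range(3)]
        statuses = push_resources(resources, mock_server)
        failed = [s for s in statuses if not s.ok]
        assert len(failed) == 1 and failed[0].resource_id == "r1"
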