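"""Task label rules: 30-day readmission, in-hospital mortality, first-24 h
imaging modalities, and after-day-one ICD categories."""

from __future__ import annotations

import dataclasses
import datetime as dt

from fhirpipe import (
    label_icd,
    label_imaging,
    label_mortality,
    label_readmission,
)
from fhirpipe.labeling import build_label_space, truncate_icd
from fhirpipe.types import ClinicalEvent, Coding, EncounterRecord, PatientRecord

from conftest import ts


_DEFAULT = object()


def _enc(eid="e1", start=None, end=_DEFAULT, pid="p1", **kw):
    return EncounterRecord(eid, pid, start or ts(2021, 3, 1, 10),
                           ts(2021, 3, 6, 9) if end is _DEFAULT else end, **kw)


def _shift_days(enc, days):
    delta = dt.timedelta(days=days)
    return dataclasses.replace(enc, start=enc.start + delta,
                               end=None if enc.end is None else enc.end + delta)


class TestReadmission:
    def test_within_thirty_days_true(self):
        index = _enc("e1")
        follow = _enc("e2", start=index.end + dt.timedelta(days=20),
                      end=index.end + dt.timedelta(days=23))
        assert label_readmission(index, [index, follow]) is True

    def test_outside_thirty_days_false(self):
        index = _enc("e1")
        follow = _enc("e2", start=index.end + dt.timedelta(days=74),
                      end=index.end + dt.timedelta(days=76))
        assert label_readmission(index, [index, follow]) is False

    def test_exactly_day_thirty_inclusive(self):
        index = _enc("e1")
        follow = _enc("e2", start=index.end + dt.timedelta(days=30),
                      end=index.end + dt.timedelta(days=31))
        assert label_readmission(index, [index, follow]) is True

    def test_same_instant_as_discharge_not_counted(self):
        # strictly-after-discharge bound of the (0, 30] interval
        index = _enc("e1")
        follow = _enc("e2", start=index.end,
                      end=index.end + dt.timedelta(days=1))
        assert label_readmission(index, [index, follow]) is False

    def test_missing_end_undefined(self):
        index = _enc("e1", end=None)
        assert label_readmission(index, [index]) is None

    def test_ongoing_followup_counts(self):
        index = _enc("e1")
        follow = _enc("e2", start=index.end + dt.timedelta(days=5), end=None)
        assert label_readmission(index, [index, follow]) is True


class TestMortality:
    def test_death_inside_stay(self):
        enc = _enc()
        patient = PatientRecord("p1", deceased_datetime=enc.end - dt.timedelta(hours=2))
        assert label_mortality(enc, patient) is True

    def test_death_after_discharge(self):
        enc = _enc()
        patient = PatientRecord("p1", deceased_datetime=enc.end + dt.timedelta(days=2))
        assert label_mortality(enc, patient) is False

    def test_no_death_signal(self):
        assert label_mortality(_enc(), PatientRecord("p1")) is False

    def test_disposition_death_code(self):
        enc = _enc(died_in_encounter=True)
        assert label_mortality(enc, PatientRecord("p1")) is True


def _study(eid, when, modality="CT"):
    return ClinicalEvent(eid, "p1", "ImagingStudy", when,
                         codes=(Coding("dcm", modality),))


def _cond(eid, when, code):
    return ClinicalEvent(eid, "p1", "Condition", when,
                         codes=(Coding("icd", code),))


class TestImaging:
    def test_half_open_24h_window(self):
        enc = _enc()
        events = [_study("a", enc.start + dt.timedelta(hours=3), "CT"),
                  _study("b", enc.start + dt.timedelta(hours=30), "MR")]
        assert label_imaging(enc, events) == frozenset({"CT"})

    def test_no_imaging_empty_label(self):
        assert label_imaging(_enc(), []) == frozenset()

    def test_duplicate_modalities_deduplicated(self):
        enc = _enc()
        events = [_study("a", enc.start + dt.timedelta(hours=1)),
                  _study("b", enc.start + dt.timedelta(hours=5))]
        assert label_imaging(enc, events) == frozenset({"CT"})

    def test_exact_24h_boundary_excluded(self):
        enc = _enc()
        events = [_study("a", enc.start + dt.timedelta(hours=24))]
        assert label_imaging(enc, events) == frozenset()


class TestIcd:
    def test_window_and_truncation(self):
        enc = _enc()
        events = [_cond("a", enc.start + dt.timedelta(hours=12), "I21.0"),
                  _cond("b", enc.start + dt.timedelta(hours=40), "E11.9")]
        assert label_icd(enc, events) == frozenset({"E11"})

    def test_all_in_first_day_empty(self):
        enc = _enc()
        events = [_cond("a", enc.start + dt.timedelta(hours=5), "I21.0")]
        assert label_icd(enc, events) == frozenset()

    def test_truncate_convention(self):
        assert truncate_icd("J18.9") == "J18"
        assert truncate_icd("E86") == "E86"


class TestLabelSpace:
    def test_frequency_order_with_alphabetical_ties(self):
        labels = [frozenset({"A10", "B20"}), frozenset({"A10"}),
                  frozenset({"C30"})]
        assert build_label_space(labels) == ("A10", "B20", "C30")

    def test_cap(self):
        labels = [frozenset({f"X{i:02d}"}) for i in range(30)]
        assert len(build_label_space(labels, max_labels=10)) == 10


def test_translation_invariance(small_parsed):
    """Shifting every timestamp by a constant leaves all labels unchanged."""
    from fhirpipe import merge_encounters

    shift = dt.timedelta(days=365)
    merged = merge_encounters(small_parsed.encounters)
    by_patient = {}
    for enc in merged:
        by_patient.setdefault(enc.patient_id, []).append(enc)
    events_by_patient = {}
    for ev in small_parsed.events:
        events_by_patient.setdefault(ev.patient_id, []).append(ev)
    patients = {p.patient_id: p for p in small_parsed.patients}

    for enc in merged[:100]:
        stays = by_patient[enc.patient_id]
        events = events_by_patient.get(enc.patient_id, [])
        shifted_enc = _shift_days(enc, 365)
        shifted_stays = [_shift_days(e, 365) for e in stays]
        shifted_events = [dataclasses.replace(ev, timestamp=ev.timestamp + shift)
                          for ev in events]
        patient = patients[enc.patient_id]
        shifted_patient = dataclasses.replace(
            patient,
            deceased_datetime=None if patient.deceased_datetime is None
            else patient.deceased_datetime + shift)
        assert label_readmission(enc, stays) == label_readmission(
            shifted_enc, shifted_stays)
        assert label_mortality(enc, patient) == label_mortality(
            shifted_enc, shifted_patient)
        assert label_imaging(enc, events) == label_imaging(
            shifted_enc, shifted_events)
        assert label_icd(enc, events) == label_icd(shifted_enc, shifted_events)
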