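"""Window-to-text rendering, dedup/truncation rules, and patient-level splits."""

from __future__ import annotations

import datetime as dt
from collections import Counter

import pytest

from fhirpipe import PipelineConfig, SampleWindow, Task, assign_splits
from fhirpipe.serialization import serialize_window, split_for_patient
from fhirpipe.types import ClinicalEvent, Coding, EncounterRecord, PatientRecord, Strategy

from conftest import ts


def _patient():
    return PatientRecord("p1", birth_date=dt.date(1980, 1, 1))


def _enc():
    return EncounterRecord("e1", "p1", ts(2021, 3, 1, 8), ts(2021, 3, 6))


def _event(eid, when, rtype="Observation", code="2345-7", text=None):
    return ClinicalEvent(eid, "p1", rtype, when,
                         codes=(Coding("sys", code),), value_text=text)


def _window(events):
    ordered = sorted(events, key=lambda e: (e.timestamp, e.event_id))
    return SampleWindow("p1", "e1", Strategy.SLIDING, ts(2021, 3, 6),
                        event_ids=tuple(e.event_id for e in ordered))


def _serialize(events, **config_kw):
    config = PipelineConfig(task=Task.READMISSION, **config_kw)
    return serialize_window(_window(events), {e.event_id: e for e in events},
                            _patient(), config, encounter=_enc())


class TestSerializeWindow:
    def test_duplicate_code_same_date_collapses(self):
        events = [_event("a", ts(2021, 3, 2, 9)), _event("b", ts(2021, 3, 2, 15))]
        doc = _serialize(events)
        assert doc.n_event_lines == 1
        assert doc.text.count("2345-7") == 1

    def test_resource_flag_filtering(self):
        conditions = [_event(f"c{i}", ts(2021, 3, 2, i + 1), "Condition",
                             code=f"I1{i}.0") for i in range(3)]
        observations = [_event(f"o{i}", ts(2021, 3, 3, i + 1), code=f"99{i}-0")
                        for i in range(5)]
        flags = {t: t == "Condition" for t in
                 PipelineConfig(task=Task.READMISSION).include_resources}
        doc = _serialize(conditions + observations, include_resources=flags)
        assert doc.n_event_lines == 3

    def test_budget_smaller_than_one_line_yields_flagged_header(self):
        doc = _serialize([_event("a", ts(2021, 3, 2, 9))], max_chars=60)
        assert doc.header_only
        assert doc.text.startswith("Patient |")
        assert doc.n_event_lines == 0

    def test_truncation_drops_oldest_first(self):
        early = _event("early", ts(2021, 3, 1, 9), code="111-1")
        late = _event("late", ts(2021, 3, 5, 9), code="222-2")
        full = _serialize([early, late])
        assert "111-1" in full.text and "222-2" in full.text
        tight = _serialize([early, late], max_chars=len(full.text) - 1)
        assert "222-2" in tight.text and "111-1" not in tight.text

    def test_monotone_ablation(self):
        events = ([_event(f"c{i}", ts(2021, 3, 2, i + 1), "Condition", f"I{i}0.0")
                   for i in range(3)]
                  + [_event(f"o{i}", ts(2021, 3, 3, i + 1), code=f"88{i}-0")
                     for i in range(4)])
        all_on = _serialize(events)
        flags = {t: t != "Observation" for t in
                 PipelineConfig(task=Task.READMISSION).include_resources}
        obs_off = _serialize(events, include_resources=flags)
        assert obs_off.n_event_lines <= all_on.n_event_lines

    def test_idempotent(self):
        events = [_event("a", ts(2021, 3, 2, 9)),
                  _event("b", ts(2021, 3, 3, 9), "DiagnosticReport",
                         code="WARD", text="stable course")]
        assert _serialize(events).text == _serialize(events).text

    def test_free_text_clipped(self):
        long_text = "word " * 400
        doc = _serialize([_event("a", ts(2021, 3, 2, 9), "DiagnosticReport",
                                 text=long_text)], text_clip_chars=50)
        line = doc.text.splitlines()[1]
        assert len(line.split(" | ")[-1]) <= 50

    def test_header_carries_demographics(self):
        doc = _serialize([])
        assert doc.text.splitlines()[0] == (
            "Patient | age 40-64 | sex unknown | insurance unknown")

    def test_no_rendered_line_past_cutoff(self, small_parsed, readmission_config):
        from fhirpipe import build_dataset

        samples, _ = build_dataset(small_parsed, readmission_config)
        for sample in samples[:200]:
            cutoff_date = sample.cutoff.date().isoformat()
            for line in sample.text.splitlines()[1:]:
                assert line.split(" | ")[0] <= cutoff_date


class TestConfigValidation:
    def test_all_flags_off_rejected(self):
        from fhirpipe.types import SUPPORTED_RESOURCE_TYPES

        with pytest.raises(ValueError, match="resource flag"):
            PipelineConfig(task=Task.READMISSION,
                           include_resources={t: False for t in
                                              SUPPORTED_RESOURCE_TYPES})

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PipelineConfig(task=Task.READMISSION, split_fractions=(0.5, 0.2, 0.2))

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown resource"):
            PipelineConfig(task=Task.READMISSION,
                           include_resources={"CarePlan": True})


class TestAssignSplits:
    def test_patient_consistency(self):
        splits = assign_splits(["pa", "pa", "pb"], seed=3)
        assert splits["pa"] in ("train", "val", "test")
        assert split_for_patient("pa", (0.8, 0.1, 0.1), 3) == splits["pa"]

    def test_seed_changes_assignment_but_stays_consistent(self):
        ids = [f"p{i}" for i in range(200)]
        a = assign_splits(ids, seed=1)
        b = assign_splits(ids, seed=2)
        assert a != b
        assert assign_splits(ids, seed=1) == a

    def test_empirical_fractions_within_two_percent(self):
        ids = [f"p{i}" for i in range(10_000)]
        splits = assign_splits(ids, (0.8, 0.1, 0.1), seed=7)
        counts = Counter(splits.values())
        assert abs(counts["train"] / 10_000 - 0.8) < 0.02
        assert abs(counts["val"] / 10_000 - 0.1) < 0.02
        assert abs(counts["test"] / 10_000 - 0.1) < 0.02

    def test_patient_disjoint_splits(self, small_parsed, readmission_config):
        from fhirpipe import build_dataset

        samples, _ = build_dataset(small_parsed, readmission_config)
        by_split: dict[str, set] = {}
        for s in samples:
            by_split.setdefault(s.split, set()).add(s.patient_id)
        splits = list(by_split.values())
        for i in range(len(splits)):
            for j in range(i + 1, len(splits)):
                assert not (splits[i] & splits[j])
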