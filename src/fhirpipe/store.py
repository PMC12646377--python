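"""Columnar persistence of pipeline artifacts.

Records travel between CLI stages as parquet files (nested fields as JSON
strings); serialized datasets are written both as parquet and as canonical
JSON-lines, the latter with sorted keys so that identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from ._time import parse_datetime, to_fhir_instant
from .fhir_io import ParseResult
from .pipeline import PreparedData
from .serialization import SerializedSample
from .types import (
    ClinicalEvent,
    Coding,
    EncounterRecord,
    Insurance,
    LabelKind,
    PatientRecord,
    SampleWindow,
    Sex,
    Strategy,
    Task,
    TaskLabel,
)


def _iso(value: Optional[dt.datetime]) -> Optional[str]:
    return to_fhir_instant(value) if value is not None else None


# --------------------------------------------------------------------------
# parsed records <-> frames


def parsed_to_frames(parsed: ParseResult) -> dict[str, pd.DataFrame]:
    patients = pd.DataFrame([{
        "patient_id": p.patient_id,
        "birth_date": p.birth_date.isoformat() if p.birth_date else None,
        "sex": p.sex.value,
        "insurance": p.insurance.value,
        "deceased_datetime": _iso(p.deceased_datetime),
    } for p in parsed.patients])
    encounters = pd.DataFrame([{
        "encounter_id": e.encounter_id,
        "patient_id": e.patient_id,
        "start": _iso(e.start),
        "end": _iso(e.end),
        "encounter_class": e.encounter_class,
        "discharge_disposition": e.discharge_disposition,
        "died_in_encounter": e.died_in_encounter,
        "merged_ids": json.dumps(list(e.merged_ids)),
    } for e in parsed.encounters])
    events = pd.DataFrame([{
        "event_id": ev.event_id,
        "patient_id": ev.patient_id,
        "encounter_id": ev.encounter_id,
        "resource_type": ev.resource_type,
        "timestamp": _iso(ev.timestamp),
        "codes": json.dumps([[c.system, c.code, c.display] for c in ev.codes]),
        "value_text": ev.value_text,
        "value_quantity": json.dumps(list(ev.value_quantity))
        if ev.value_quantity else None,
    } for ev in parsed.events])
    return {"patients": patients, "encounters": encounters, "events": events}


def frames_to_parsed(frames: dict[str, pd.DataFrame]) -> ParseResult:
    patients = []
    for row in frames["patients"].itertuples():
        birth = parse_datetime(row.birth_date) if row.birth_date else None
        patients.append(PatientRecord(
            patient_id=row.patient_id,
            birth_date=birth.date() if birth else None,
            sex=Sex(row.sex),
            insurance=Insurance(row.insurance),
            deceased_datetime=parse_datetime(row.deceased_datetime)
            if row.deceased_datetime else None,
        ))
    encounters = []
    for row in frames["encounters"].itertuples():
        encounters.append(EncounterRecord(
            encounter_id=row.encounter_id,
            patient_id=row.patient_id,
            start=parse_datetime(row.start),
            end=parse_datetime(row.end) if row.end else None,
            encounter_class=row.encounter_class,
            discharge_disposition=row.discharge_disposition,
            died_in_encounter=bool(row.died_in_encounter),
            merged_ids=tuple(json.loads(row.merged_ids)),
        ))
    events = []
    for row in frames["events"].itertuples():
        quantity = None
        if row.value_quantity:
            number, unit = json.loads(row.value_quantity)
            quantity = (float(number), unit)
        events.append(ClinicalEvent(
            event_id=row.event_id,
            patient_id=row.patient_id,
            encounter_id=row.encounter_id if pd.notna(row.encounter_id) else None,
            resource_type=row.resource_type,
            timestamp=parse_datetime(row.timestamp),
            codes=tuple(Coding(s, c, d) for s, c, d in json.loads(row.codes)),
            value_text=row.value_text if pd.notna(row.value_text) else None,
            value_quantity=quantity,
        ))
    return ParseResult(patients, encounters, events, 0)


def save_parsed(parsed: ParseResult, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in parsed_to_frames(parsed).items():
        path = out_dir / f"{name}.parquet"
        frame.to_parquet(path, index=False)
        written.append(path)
    return written


def load_parsed(in_dir: Path) -> ParseResult:
    in_dir = Path(in_dir)
    frames = {name: pd.read_parquet(in_dir / f"{name}.parquet").where(
        lambda df: df.notna(), None)
        for name in ("patients", "encounters", "events")}
    return frames_to_parsed(frames)


# --------------------------------------------------------------------------
# prepared windows/labels <-> frame


def _label_to_json(label: TaskLabel) -> str:
    if label.kind is LabelKind.BINARY:
        return json.dumps(bool(label.value))
    return json.dumps(sorted(label.value))


def _label_from_json(task: Task, kind: LabelKind, payload: str,
                     label_space: tuple[str, ...]) -> TaskLabel:
    value = json.loads(payload)
    if kind is LabelKind.BINARY:
        return TaskLabel(task, kind, bool(value))
    return TaskLabel(task, kind, frozenset(value), label_space)


def save_prepared(prepared: PreparedData, path: Path) -> None:
    rows = []
    for window, label in zip(prepared.windows, prepared.labels):
        rows.append({
            "window_id": window.window_id,
            "patient_id": window.patient_id,
            "encounter_id": window.encounter_id,
            "strategy": window.strategy.value,
            "cutoff": _iso(window.cutoff),
            "history_start": _iso(window.history_start),
            "day_index": window.day_index,
            "event_ids": json.dumps(list(window.event_ids)),
            "label": _label_to_json(label),
            "split": prepared.splits[window.window_id],
        })
    frame = pd.DataFrame(rows)
    frame.attrs = {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_parquet(path, index=False)
    meta = {
        "task": prepared.task.value,
        "kind": prepared.kind.value,
        "label_space": list(prepared.label_space),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))


def load_prepared(samples_path: Path, parsed: ParseResult) -> PreparedData:
    from .fhir_io import merge_encounters

    samples_path = Path(samples_path)
    meta = json.loads(samples_path.with_suffix(".meta.json").read_text())
    task = Task(meta["task"])
    kind = LabelKind(meta["kind"])
    label_space = tuple(meta["label_space"])
    frame = pd.read_parquet(samples_path)
    windows, labels, splits = [], [], {}
    for row in frame.itertuples():
        window = SampleWindow(
            patient_id=row.patient_id,
            encounter_id=row.encounter_id,
            strategy=Strategy(row.strategy),
            cutoff=parse_datetime(row.cutoff),
            history_start=parse_datetime(row.history_start)
            if row.history_start else None,
            event_ids=tuple(json.loads(row.event_ids)),
            day_index=int(row.day_index) if pd.notna(row.day_index) else None,
        )
        windows.append(window)
        labels.append(_label_from_json(task, kind, row.label, label_space))
        splits[window.window_id] = row.split
    merged = merge_encounters(parsed.encounters)
    return PreparedData(
        task=task, kind=kind, windows=windows, labels=labels,
        label_space=label_space,
        patients_by_id={p.patient_id: p for p in parsed.patients},
        encounters_by_id={e.encounter_id: e for e in merged},
        events_by_id={e.event_id: e for e in parsed.events},
        splits=splits,
    )


# --------------------------------------------------------------------------
# serialized datasets


def samples_to_jsonl(samples: Sequence[SerializedSample]) -> str:
    lines = []
    for s in samples:
        lines.append(json.dumps({
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "encounter_id": s.encounter_id,
            "text": s.text,
            "label": json.loads(_label_to_json(s.label)),
            "split": s.split,
            "cutoff": _iso(s.cutoff),
            "header_only": s.header_only,
        }, sort_keys=True))
    return "\n".join(lines)


def save_dataset(samples: Sequence[SerializedSample],
                 label_space: tuple[str, ...],
                 task: Task, kind: LabelKind, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "dataset.jsonl").write_text(samples_to_jsonl(samples))
    frame = pd.DataFrame([{
        "sample_id": s.sample_id, "patient_id": s.patient_id,
        "encounter_id": s.encounter_id, "text": s.text,
        "label": _label_to_json(s.label), "split": s.split,
        "cutoff": _iso(s.cutoff), "header_only": s.header_only,
    } for s in samples])
    frame.to_parquet(out_dir / "dataset.parquet", index=False)
    (out_dir / "label_space.json").write_text(json.dumps({
        "task": task.value, "kind": kind.value,
        "label_space": list(label_space),
    }, sort_keys=True))


def load_dataset(in_dir: Path) -> tuple[list[SerializedSample], tuple[str, ...],
                                        Task, LabelKind]:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "label_space.json").read_text())
    task = Task(meta["task"])
    kind = LabelKind(meta["kind"])
    label_space = tuple(meta["label_space"])
    samples = []
    for line in (in_dir / "dataset.jsonl").read_text().splitlines():
        row = json.loads(line)
        samples.append(SerializedSample(
            sample_id=row["sample_id"], patient_id=row["patient_id"],
            encounter_id=row["encounter_id"], text=row["text"],
            label=_label_from_json(task, kind, json.dumps(row["label"]),
                                   label_space),
            split=row["split"], cutoff=parse_datetime(row["cutoff"]),
            header_only=row["header_only"],
        ))
    return samples, label_space, task, kind
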