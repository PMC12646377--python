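"""End-to-end glue: parsed records -> windows -> labels -> text -> model.

Task-specific window cutoffs keep features and labels temporally disjoint:

==============  ==========================  ==================================
task            sliding-window cutoff       label-defining interval
==============  ==========================  ==================================
readmission     discharge                   (discharge, discharge + 30 d]
mortality       discharge                   death signal on the stay itself
imaging         admission                   [admission, admission + 24 h)
icd             admission + 24 h            (admission + 24 h, discharge]
==============  ==========================  ==================================

Expanding windows are supported for the outcome-at-discharge tasks
(readmission, mortality), where every daily cutoff precedes the label
interval; for imaging/icd the daily cutoffs would overlap the label window,
so those combinations are rejected.

Multilabel label spaces are derived from the training split only and then
applied to every split, mirroring deployment-time alignment.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
from typing import Optional, Sequence

from ._time import HOURS_24
from . import labeling, sampling
from .cohort import CohortSpec, apply_inclusion
from .fhir_io import ParseResult, merge_encounters
from .modeling import (
    BackendSpec,
    BagOfWordsLinearModel,
    MetricsReport,
    binarize_labels,
    evaluate,
    train,
)
from .serialization import (
    PipelineConfig,
    SerializedSample,
    serialize_window,
    split_for_patient,
)
from .types import (
    ClinicalEvent,
    EncounterRecord,
    LabelKind,
    PatientRecord,
    SampleWindow,
    Strategy,
    Task,
    TaskLabel,
)

TASK_KIND = {
    Task.READMISSION: LabelKind.BINARY,
    Task.MORTALITY: LabelKind.BINARY,
    Task.IMAGING: LabelKind.MULTILABEL,
    Task.ICD: LabelKind.MULTILABEL,
}

#: Tasks whose label interval lies inside the stay; daily expanding cutoffs
#: would overlap it.
_SLIDING_ONLY = (Task.IMAGING, Task.ICD)


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out, always below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def task_cutoff(task: Task, encounter: EncounterRecord) -> Optional[dt.datetime]:
    task = Task(task)
    if task is Task.IMAGING:
        return encounter.start
    if task is Task.ICD:
        return encounter.start + HOURS_24
    return encounter.end


@dataclasses.dataclass
class PreparedData:
    """Windows, labels and splits with serialization deferred, so sweeps can
    re-render the same samples under different resource flags cheaply."""

    task: Task
    kind: LabelKind
    windows: list[SampleWindow]
    labels: list[TaskLabel]
    label_space: tuple[str, ...]
    patients_by_id: dict[str, PatientRecord]
    encounters_by_id: dict[str, EncounterRecord]
    events_by_id: dict[str, ClinicalEvent]
    splits: dict[str, str]  # window_id -> split


def prepare(
    parsed: ParseResult,
    config: PipelineConfig,
    cohort_spec: Optional[CohortSpec] = None,
    max_label_space: int = 100,
) -> PreparedData:
    """Cohort -> windows -> labels -> splits for one task/strategy."""
    task = Task(config.task)
    strategy = Strategy(config.strategy)
    kind = TASK_KIND[task]
    if strategy is Strategy.EXPANDING and task in _SLIDING_ONLY:
        raise ValueError(
            f"expanding windows are not leakage-safe for the {task.value} task; "
            "use the sliding strategy"
        )
    merged = merge_encounters(parsed.encounters)
    spec = cohort_spec or CohortSpec.preset(task)
    eligible = set(apply_inclusion(spec, parsed.patients, merged, parsed.events))

    patients_by_id = {p.patient_id: p for p in parsed.patients}
    encounters = [e for e in merged
                  if (e.patient_id, e.encounter_id) in eligible
                  and e.patient_id in patients_by_id]
    encounters_by_id = {e.encounter_id: e for e in encounters}
    stays_by_patient: dict[str, list[EncounterRecord]] = {}
    for enc in merged:
        stays_by_patient.setdefault(enc.patient_id, []).append(enc)
    events_by_patient: dict[str, list[ClinicalEvent]] = {}
    for ev in parsed.events:
        events_by_patient.setdefault(ev.patient_id, []).append(ev)

    if strategy is Strategy.SLIDING:
        overrides = {}
        for enc in encounters:
            cutoff = task_cutoff(task, enc)
            if cutoff is not None:
                overrides[enc.encounter_id] = cutoff
        windows = sampling.sliding_windows(encounters, parsed.events,
                                           cutoff_override=overrides)
    else:
        windows = []
        for enc in sorted(encounters, key=lambda e: (e.patient_id, e.start)):
            windows.extend(sampling.expanding_windows(
                enc, events_by_patient.get(enc.patient_id, [])))

    # outcome-level labels, computed once per encounter
    label_by_encounter: dict[str, Optional[TaskLabel]] = {}
    for enc in encounters:
        label_by_encounter[enc.encounter_id] = labeling.label_window(
            task, enc, patients_by_id[enc.patient_id],
            stays_by_patient.get(enc.patient_id, []),
            events_by_patient.get(enc.patient_id, []),
        )

    kept_windows: list[SampleWindow] = []
    labels: list[TaskLabel] = []
    for window in windows:
        label = label_by_encounter.get(window.encounter_id)
        if label is None:
            continue
        kept_windows.append(window)
        labels.append(label)

    splits = {
        w.window_id: split_for_patient(w.patient_id, config.split_fractions,
                                       config.seed)
        for w in kept_windows
    }

    label_space: tuple[str, ...] = ()
    if kind is LabelKind.MULTILABEL:
        train_values = [lbl.value for w, lbl in zip(kept_windows, labels)
                        if splits[w.window_id] == "train"]
        label_space = labeling.build_label_space(train_values, max_label_space)
        labels = [
            TaskLabel(task, kind,
                      frozenset(v for v in lbl.value if v in label_space),
                      label_space)
            for lbl in labels
        ]

    return PreparedData(
        task=task, kind=kind, windows=kept_windows, labels=labels,
        label_space=label_space, patients_by_id=patients_by_id,
        encounters_by_id=encounters_by_id,
        events_by_id={e.event_id: e for e in parsed.events},
        splits=splits,
    )


def materialize(prepared: PreparedData,
                config: PipelineConfig) -> list[SerializedSample]:
    """Render every window into a SerializedSample under the given config."""
    samples: list[SerializedSample] = []
    for window, label in zip(prepared.windows, prepared.labels):
        doc = serialize_window(
            window, prepared.events_by_id,
            prepared.patients_by_id[window.patient_id], config,
            encounter=prepared.encounters_by_id.get(window.encounter_id),
        )
        samples.append(SerializedSample(
            sample_id=window.window_id,
            patient_id=window.patient_id,
            encounter_id=window.encounter_id,
            text=doc.text,
            label=label,
            split=prepared.splits[window.window_id],
            cutoff=window.cutoff,
            header_only=doc.header_only,
        ))
    return samples


def build_dataset(
    parsed: ParseResult,
    config: PipelineConfig,
    cohort_spec: Optional[CohortSpec] = None,
    max_label_space: int = 100,
) -> tuple[list[SerializedSample], tuple[str, ...]]:
    """One-call dataset construction: returns samples and the label space."""
    prepared = prepare(parsed, config, cohort_spec, max_label_space)
    return materialize(prepared, config), prepared.label_space


@dataclasses.dataclass
class FitResult:
    model: BagOfWordsLinearModel
    reports: dict[str, MetricsReport]
    label_space: tuple[str, ...]
    kind: LabelKind


def fit_and_score(
    samples: Sequence[SerializedSample],
    kind: LabelKind,
    label_space: tuple[str, ...] = (),
    backend: Optional[BackendSpec] = None,
    k: int = 10,
    eval_splits: tuple[str, ...] = ("train", "val", "test"),
) -> FitResult:
    """Train on the train split and evaluate each requested split."""
    backend = backend or BackendSpec()
    by_split: dict[str, list[SerializedSample]] = {}
    for s in samples:
        by_split.setdefault(s.split, []).append(s)
    train_samples = by_split.get("train", [])
    model = train([s.text for s in train_samples],
                  [s.label for s in train_samples],
                  kind, backend, label_space)
    reports: dict[str, MetricsReport] = {}
    for split in eval_splits:
        subset = by_split.get(split, [])
        if not subset:
            continue
        probs = model.predict_proba([s.text for s in subset])
        if kind is LabelKind.BINARY:
            y = [bool(s.label.value) for s in subset]
        else:
            y = binarize_labels([s.label for s in subset], label_space)
        reports[split] = evaluate(y, probs, kind, threshold=backend.threshold,
                                  k=k, label_space=label_space)
    return FitResult(model=model, reports=reports, label_space=tuple(label_space),
                     kind=kind)
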