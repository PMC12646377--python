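"""Task label computation for sample windows.

Four tasks, two single-label and two multi-label:

* readmission — true iff another merged stay of the same patient starts in
  (discharge, discharge + 30 days]; strictly after discharge, inclusive
  30th day;
* mortality — true iff the patient dies during the stay (deceased timestamp
  inside [admission, discharge] or a death discharge-disposition code);
* imaging — the set of DICOM modality codes of imaging studies started in
  [admission, admission + 24 h), a half-open window;
* icd — the set of ICD condition codes recorded in (admission + 24 h,
  discharge], truncated to the 3-character category by default.

Labels are outcome-level: for expanding windows they are computed once per
encounter and attached to each daily window, whose features remain
cutoff-limited.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter
from typing import Optional, Sequence

from ._time import HOURS_24
from .cohort import DEFAULT_MAIN_DIAGNOSIS_CODES
from .types import (
    ClinicalEvent,
    EncounterRecord,
    LabelKind,
    PatientRecord,
    Task,
    TaskLabel,
)

logger = logging.getLogger(__name__)

READMISSION_DAYS = 30


def label_readmission(
    encounter: EncounterRecord,
    patient_encounters: Sequence[EncounterRecord],
) -> Optional[bool]:
    """30-day readmission: a later merged stay starting in (end, end + 30 d].

    Returns None (sample dropped by the caller) when the index stay has no
    discharge timestamp.
    """
    if encounter.end is None:
        logger.warning("encounter %s has no end; readmission label undefined",
                       encounter.encounter_id)
        return None
    horizon = encounter.end + dt.timedelta(days=READMISSION_DAYS)
    for other in patient_encounters:
        if other.encounter_id == encounter.encounter_id:
            continue
        if other.patient_id != encounter.patient_id:
            continue
        if encounter.end < other.start <= horizon:
            return True
    return False


def label_mortality(encounter: EncounterRecord, patient: PatientRecord) -> bool:
    """In-hospital mortality: death timestamp within the stay, or a death
    discharge-disposition code on the encounter."""
    if encounter.died_in_encounter:
        return True
    deceased = patient.deceased_datetime
    if deceased is None:
        return False
    if encounter.end is not None:
        return encounter.start <= deceased <= encounter.end
    return deceased >= encounter.start


def label_imaging(
    encounter: EncounterRecord,
    events: Sequence[ClinicalEvent],
) -> frozenset[str]:
    """Modalities of imaging studies started within the first 24 hours of
    admission (half-open [start, start + 24 h)); the empty set is legal."""
    cutoff = encounter.start + HOURS_24
    modalities: set[str] = set()
    for ev in events:
        if ev.resource_type != "ImagingStudy" or ev.patient_id != encounter.patient_id:
            continue
        if encounter.start <= ev.timestamp < cutoff:
            modalities.update(c.code for c in ev.codes)
    return frozenset(modalities)


def truncate_icd(code: str, length: int = 3) -> str:
    """'J18.9' -> 'J18' under the default 3-character category truncation."""
    return code.split(".", 1)[0][:length]


def label_icd(
    encounter: EncounterRecord,
    events: Sequence[ClinicalEvent],
    truncate_to: int = 3,
    exclude_main_diagnosis: bool = False,
) -> frozenset[str]:
    """ICD condition codes recorded after the first day of admission until
    discharge: timestamps in (start + 24 h, end]."""
    if encounter.end is None:
        return frozenset()
    lower = encounter.start + HOURS_24
    codes: set[str] = set()
    for ev in events:
        if ev.resource_type != "Condition" or ev.patient_id != encounter.patient_id:
            continue
        if not (lower < ev.timestamp <= encounter.end):
            continue
        if exclude_main_diagnosis and any(
            c.code in DEFAULT_MAIN_DIAGNOSIS_CODES for c in ev.codes
        ):
            continue
        primary = ev.code
        if primary is not None and primary.code not in DEFAULT_MAIN_DIAGNOSIS_CODES:
            codes.add(truncate_icd(primary.code, truncate_to))
    return frozenset(codes)


def build_label_space(
    labels: Sequence[frozenset[str]],
    max_labels: int = 100,
) -> tuple[str, ...]:
    """Order the multilabel vocabulary by training-split frequency, capped to
    the ``max_labels`` most frequent codes; ties broken alphabetically."""
    counts = Counter(code for label in labels for code in label)
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return tuple(code for code, _ in ranked[:max_labels])


def label_window(
    task: Task,
    encounter: EncounterRecord,
    patient: PatientRecord,
    patient_encounters: Sequence[EncounterRecord],
    events: Sequence[ClinicalEvent],
    label_space: tuple[str, ...] = (),
    icd_truncate_to: int = 3,
    exclude_main_diagnosis: bool = False,
) -> Optional[TaskLabel]:
    """Dispatch to the task-specific rule; None means the sample is dropped."""
    task = Task(task)
    if task is Task.READMISSION:
        value = label_readmission(encounter, patient_encounters)
        if value is None:
            return None
        return TaskLabel(task, LabelKind.BINARY, value)
    if task is Task.MORTALITY:
        return TaskLabel(task, LabelKind.BINARY, label_mortality(encounter, patient))
    if task is Task.IMAGING:
        value = label_imaging(encounter, events)
    else:
        value = label_icd(encounter, events, icd_truncate_to, exclude_main_diagnosis)
    if label_space:
        value = frozenset(v for v in value if v in label_space)
    return TaskLabel(task, LabelKind.MULTILABEL, value, tuple(label_space))
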