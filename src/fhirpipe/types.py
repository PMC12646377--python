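"""Domain records shared by every pipeline stage.

The pipeline's atoms are deliberately small, serializable dataclasses:

* :class:`PatientRecord` / :class:`EncounterRecord` — demographics and
  inpatient stays, the units of cohort rules and windowing;
* :class:`ClinicalEvent` — one timestamped, coded, optionally free-text
  clinical fact extracted from any supported FHIR resource;
* :class:`SampleWindow` — a (patient, encounter, cutoff) view of the
  timeline under a sampling strategy;
* :class:`TaskLabel` — the binary or multi-label target of a window;
* :class:`RiskAssessmentRecord` — a prediction ready to be rendered as a
  FHIR R4 RiskAssessment.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from typing import Optional


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Insurance(str, enum.Enum):
    STATUTORY = "statutory"
    PRIVATE = "private"
    UNKNOWN = "unknown"


class Task(str, enum.Enum):
    READMISSION = "readmission"
    MORTALITY = "mortality"
    IMAGING = "imaging"
    ICD = "icd"


class Strategy(str, enum.Enum):
    SLIDING = "sliding"
    EXPANDING = "expanding"


#: The ten supported FHIR resource types. The Medication family
#: (MedicationStatement / MedicationAdministration / MedicationRequest)
#: normalizes to the single canonical member "Medication".
SUPPORTED_RESOURCE_TYPES = (
    "Patient",
    "Encounter",
    "Condition",
    "Procedure",
    "Observation",
    "ImagingStudy",
    "DiagnosticReport",
    "EpisodeOfCare",
    "ServiceRequest",
    "Medication",
)

#: Raw resourceType values accepted on input, mapped to canonical names.
RESOURCE_TYPE_ALIASES = {
    "MedicationStatement": "Medication",
    "MedicationAdministration": "Medication",
    "MedicationRequest": "Medication",
    "Medication": "Medication",
}

#: Event-bearing types (everything except the record types Patient/Encounter).
EVENT_RESOURCE_TYPES = tuple(
    t for t in SUPPORTED_RESOURCE_TYPES if t not in ("Patient", "Encounter")
)


@dataclasses.dataclass(frozen=True)
class Coding:
    """A (system, code, display) triple."""

    system: Optional[str]
    code: str
    display: Optional[str] = None

    @property
    def label(self) -> str:
        return self.display or self.code


@dataclasses.dataclass
class PatientRecord:
    patient_id: str
    birth_date: Optional[dt.date] = None
    sex: Sex = Sex.UNKNOWN
    insurance: Insurance = Insurance.UNKNOWN
    deceased_datetime: Optional[dt.datetime] = None


@dataclasses.dataclass
class EncounterRecord:
    encounter_id: str
    patient_id: str
    start: dt.datetime
    end: Optional[dt.datetime] = None
    encounter_class: Optional[str] = None
    discharge_disposition: Optional[str] = None
    died_in_encounter: bool = False
    #: ids of raw encounters collapsed into this merged stay (self included)
    merged_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.merged_ids:
            self.merged_ids = (self.encounter_id,)
        if self.end is not None and self.end < self.start:
            raise ValueError(
                f"encounter {self.encounter_id}: end {self.end} before start {self.start}"
            )


@dataclasses.dataclass
class ClinicalEvent:
    event_id: str
    patient_id: str
    resource_type: str
    timestamp: dt.datetime
    encounter_id: Optional[str] = None
    codes: tuple[Coding, ...] = ()
    value_text: Optional[str] = None
    value_quantity: Optional[tuple[float, Optional[str]]] = None

    def __post_init__(self) -> None:
        if self.resource_type not in SUPPORTED_RESOURCE_TYPES:
            raise ValueError(f"unsupported resource_type {self.resource_type!r}")

    @property
    def code(self) -> Optional[Coding]:
        """Primary coding, or None if the event carries no code."""
        return self.codes[0] if self.codes else None


@dataclasses.dataclass
class SampleWindow:
    patient_id: str
    encounter_id: str
    strategy: Strategy
    cutoff: dt.datetime
    event_ids: tuple[str, ...] = ()
    history_start: Optional[dt.datetime] = None
    day_index: Optional[int] = None  # 1-based, expanding windows only

    @property
    def window_id(self) -> str:
        day = "" if self.day_index is None else f":d{self.day_index}"
        return f"{self.encounter_id}:{self.strategy.value}{day}"


class LabelKind(str, enum.Enum):
    BINARY = "binary"
    MULTILABEL = "multilabel"


@dataclasses.dataclass
class TaskLabel:
    task: Task
    kind: LabelKind
    value: object  # bool for binary, frozenset[str] for multilabel
    label_space: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind is LabelKind.BINARY:
            if self.label_space:
                raise ValueError("binary labels carry no label_space")
            if not isinstance(self.value, bool):
                raise TypeError("binary label value must be bool")
        else:
            self.value = frozenset(self.value)


@dataclasses.dataclass
class RiskAssessmentRecord:
    subject: str
    task: Task
    probability: float
    outcome_code: str
    occurrence: dt.datetime
    model_version: str
    encounter: Optional[str] = None
    basis: tuple[str, ...] = ()
    assessment_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.subject:
            raise ValueError("subject reference must be non-empty")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")
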