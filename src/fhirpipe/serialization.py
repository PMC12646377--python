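"""Config-driven rendering of sample windows into text documents.

A window becomes one document: a fixed header line with demographics (age
band, sex, insurance), then one pipe-delimited line per visible event —

    <ISO date> | <resource type> | <code display or code> | <value or text>

Only events whose resource-type flag is enabled are rendered, in sort-key
order (timestamp by default); duplicates under the dedup keys (resource
type + primary code + calendar date by default) collapse to the earliest
occurrence; free-text payloads are clipped per event; over a character
budget, the oldest lines are dropped first — the most recent clinical state
is the most predictive for these tasks, and a character budget keeps the
core tokenizer-independent.

Split assignment hashes (seed, patient_id), so every sample of a patient
lands in the same split and train/val/test patient sets are disjoint by
construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Optional, Sequence

from .cohort import age_band
from ._time import floored_age_years
from .types import (
    ClinicalEvent,
    EncounterRecord,
    PatientRecord,
    SampleWindow,
    Strategy,
    SUPPORTED_RESOURCE_TYPES,
    Task,
    TaskLabel,
)

SPLITS = ("train", "val", "test")


def default_resource_flags() -> dict[str, bool]:
    return {rtype: True for rtype in SUPPORTED_RESOURCE_TYPES}


@dataclasses.dataclass
class PipelineConfig:
    task: Task = Task.READMISSION
    include_resources: dict[str, bool] = dataclasses.field(
        default_factory=default_resource_flags)
    sort_keys: tuple[str, ...] = ("timestamp",)
    dedup_keys: tuple[str, ...] = ("resource_type", "code", "date")
    max_chars: int = 2048  # ~512 encoder tokens at ~4 chars/token
    text_clip_chars: int = 500
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    strategy: Strategy = Strategy.SLIDING
    backend: str = "bag_of_words_linear"
    model_name: str = ""

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.strategy = Strategy(self.strategy)
        self.sort_keys = tuple(self.sort_keys)
        self.dedup_keys = tuple(self.dedup_keys)
        self.split_fractions = tuple(self.split_fractions)
        flags = dict(default_resource_flags())
        flags.update(self.include_resources)
        unknown = set(flags) - set(SUPPORTED_RESOURCE_TYPES)
        if unknown:
            raise ValueError(f"unknown resource flags: {sorted(unknown)}")
        self.include_resources = flags
        if not any(self.include_resources.values()):
            raise ValueError("at least one resource flag must be enabled")
        if len(self.split_fractions) != 3 or any(f <= 0 for f in self.split_fractions):
            raise ValueError("split_fractions must be three positive numbers")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.max_chars <= 0:
            raise ValueError("max_chars must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"] = self.task.value
        d["strategy"] = self.strategy.value
        d["sort_keys"] = list(self.sort_keys)
        d["dedup_keys"] = list(self.dedup_keys)
        d["split_fractions"] = list(self.split_fractions)
        return d


@dataclasses.dataclass
class SerializedSample:
    sample_id: str
    patient_id: str
    encounter_id: str
    text: str
    label: Optional[TaskLabel]
    split: str
    cutoff: object
    header_only: bool = False


def _event_value(event: ClinicalEvent, clip: int) -> str:
    if event.value_quantity is not None:
        number, unit = event.value_quantity
        return f"{number:g} {unit}" if unit else f"{number:g}"
    if event.value_text:
        text = " ".join(event.value_text.split())
        return text[:clip]
    return ""


def _render_line(event: ClinicalEvent, clip: int) -> str:
    code = event.code
    label = code.label if code else ""
    if len(event.codes) > 1 and event.resource_type == "ImagingStudy":
        label = " ".join(sorted(c.code for c in event.codes))
    return " | ".join([
        event.timestamp.date().isoformat(),
        event.resource_type,
        label,
        _event_value(event, clip),
    ])


def _sort_value(event: ClinicalEvent, key: str):
    if key == "timestamp":
        return event.timestamp
    if key == "resource_type":
        return event.resource_type
    if key == "code":
        return event.code.code if event.code else ""
    if key == "date":
        return event.timestamp.date()
    raise ValueError(f"unknown sort key {key!r}")


def _dedup_value(event: ClinicalEvent, key: str):
    if key == "date":
        return event.timestamp.date()
    return _sort_value(event, key)


def render_header(patient: PatientRecord,
                  encounter: Optional[EncounterRecord]) -> str:
    if patient.birth_date is not None and encounter is not None:
        band = age_band(floored_age_years(patient.birth_date, encounter.start))
    else:
        band = "unknown"
    return (f"Patient | age {band} | sex {patient.sex.value} | "
            f"insurance {patient.insurance.value}")


@dataclasses.dataclass
class SerializedDocument:
    text: str
    header_only: bool
    n_event_lines: int


def serialize_window(
    window: SampleWindow,
    events_by_id: dict[str, ClinicalEvent],
    patient: PatientRecord,
    config: PipelineConfig,
    encounter: Optional[EncounterRecord] = None,
) -> SerializedDocument:
    """Render one window into a text document under the config's rules."""
    events = [events_by_id[eid] for eid in window.event_ids if eid in events_by_id]
    events = [e for e in events if config.include_resources.get(e.resource_type, False)]

    # dedup: keep the earliest occurrence of each key
    events.sort(key=lambda e: (e.timestamp, e.event_id))
    seen: set = set()
    kept: list[ClinicalEvent] = []
    for ev in events:
        key = tuple(_dedup_value(ev, k) for k in config.dedup_keys)
        if key in seen:
            continue
        seen.add(key)
        kept.append(ev)

    kept.sort(key=lambda e: tuple(_sort_value(e, k) for k in config.sort_keys)
              + (e.timestamp, e.event_id))

    header = render_header(patient, encounter)
    lines = [(ev.timestamp, ev.event_id, _render_line(ev, config.text_clip_chars))
             for ev in kept]

    def doc_length(active: list) -> int:
        return len(header) + sum(len(text) + 1 for _, _, text in active)

    # over budget: drop oldest event lines first; header always survives
    active = list(lines)
    while active and doc_length(active) > config.max_chars:
        oldest = min(active, key=lambda item: (item[0], item[1]))
        active.remove(oldest)

    header_only = not active
    text = "\n".join([header] + [t for _, _, t in active])
    return SerializedDocument(text=text, header_only=header_only,
                              n_event_lines=len(active))


def split_for_patient(patient_id: str, fractions: Sequence[float], seed: int) -> str:
    """Deterministic hash of (seed, patient_id) into train/val/test."""
    digest = hashlib.sha256(f"{seed}:{patient_id}".encode("utf-8")).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    if u < fractions[0]:
        return "train"
    if u < fractions[0] + fractions[1]:
        return "val"
    return "test"


def assign_splits(
    patient_ids: Sequence[str],
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, str]:
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive and sum to 1")
    return {pid: split_for_patient(pid, fractions, seed) for pid in set(patient_ids)}
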