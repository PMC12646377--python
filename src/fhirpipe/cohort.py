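"""Task-specific cohort inclusion criteria and demographic summaries.

Four built-in presets encode the inclusion rules of the four prediction
tasks:

* readmission — only patients with multiple (merged) hospital stays;
* mortality  — patients with at least one admission (an ``exactly_one``
  switch restricts to single-admission patients, since "a single hospital
  admission" is ambiguous between the two readings);
* imaging    — encounters with at least one imaging study during the stay;
* icd        — stays of at least two days with at least one recorded
  condition and a main diagnosis.

Stay length in days is the ceiling of (end - start) / 24 h; age is taken at
encounter start, floored to whole years.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import statistics
from typing import Optional, Sequence

from ._time import floored_age_years, stay_length_days
from .types import (
    ClinicalEvent,
    EncounterRecord,
    Insurance,
    PatientRecord,
    Sex,
    Task,
)

#: Diagnosis-role / category codes accepted as "main diagnosis" markers.
DEFAULT_MAIN_DIAGNOSIS_CODES = frozenset({"CC", "AD", "hauptdiagnose", "principal"})

AGE_BANDS = ("<18", "18-39", "40-64", "65-99", ">=100")


def age_band(age_years: int) -> str:
    if age_years < 18:
        return "<18"
    if age_years <= 39:
        return "18-39"
    if age_years <= 64:
        return "40-64"
    if age_years <= 99:
        return "65-99"
    return ">=100"


@dataclasses.dataclass
class CohortSpec:
    task: Task
    min_stay_days: int = 0
    requires_multiple_stays: bool = False
    requires_imaging: bool = False
    requires_condition_and_main_dx: bool = False
    exactly_one_stay: bool = False
    main_diagnosis_codes: frozenset = DEFAULT_MAIN_DIAGNOSIS_CODES

    @classmethod
    def preset(cls, task: Task, exactly_one_stay: bool = False) -> "CohortSpec":
        task = Task(task)
        if task is Task.READMISSION:
            return cls(task, requires_multiple_stays=True)
        if task is Task.MORTALITY:
            return cls(task, exactly_one_stay=exactly_one_stay)
        if task is Task.IMAGING:
            return cls(task, requires_imaging=True)
        return cls(Task.ICD, min_stay_days=2, requires_condition_and_main_dx=True)


def is_main_diagnosis(event: ClinicalEvent,
                      accepted: frozenset = DEFAULT_MAIN_DIAGNOSIS_CODES) -> bool:
    """A Condition is a main diagnosis if any of its codings carries an
    accepted diagnosis-role code."""
    return event.resource_type == "Condition" and any(
        c.code in accepted for c in event.codes
    )


def _events_in_stay(encounter: EncounterRecord,
                    events: Sequence[ClinicalEvent]) -> list[ClinicalEvent]:
    """Events linked to the stay by encounter id or by time containment."""
    ids = set(encounter.merged_ids)
    out = []
    for ev in events:
        if ev.patient_id != encounter.patient_id:
            continue
        if ev.encounter_id is not None:
            if ev.encounter_id in ids:
                out.append(ev)
        elif encounter.end is not None and encounter.start <= ev.timestamp <= encounter.end:
            out.append(ev)
    return out


def apply_inclusion(
    spec: CohortSpec,
    patients: Sequence[PatientRecord],
    encounters: Sequence[EncounterRecord],
    events: Sequence[ClinicalEvent],
) -> list[tuple[str, str]]:
    """Return eligible (patient_id, encounter_id) pairs.

    ``encounters`` must already be merged stays. Empty output is legal.
    """
    known = {p.patient_id for p in patients}
    stays_per_patient: dict[str, int] = {}
    for enc in encounters:
        stays_per_patient[enc.patient_id] = stays_per_patient.get(enc.patient_id, 0) + 1

    eligible: list[tuple[str, str]] = []
    for enc in encounters:
        if enc.patient_id not in known:
            continue
        n_stays = stays_per_patient[enc.patient_id]
        if spec.requires_multiple_stays and n_stays < 2:
            continue
        if spec.exactly_one_stay and n_stays != 1:
            continue
        if spec.min_stay_days > 0:
            if enc.end is None or stay_length_days(enc.start, enc.end) < spec.min_stay_days:
                continue
        if spec.requires_imaging or spec.requires_condition_and_main_dx:
            stay_events = _events_in_stay(enc, events)
            if spec.requires_imaging:
                if not any(e.resource_type == "ImagingStudy" for e in stay_events):
                    continue
            if spec.requires_condition_and_main_dx:
                conditions = [e for e in stay_events if e.resource_type == "Condition"]
                if not conditions:
                    continue
                if not any(is_main_diagnosis(e, spec.main_diagnosis_codes)
                           for e in conditions):
                    continue
        eligible.append((enc.patient_id, enc.encounter_id))
    eligible.sort()
    return eligible


@dataclasses.dataclass
class CohortSummary:
    n_patients: int
    n_samples: int
    age_band_counts: dict[str, int]
    age_unknown: int
    sex_counts: dict[str, int]
    insurance_counts: dict[str, int]
    mortality_count: int
    mortality_rate: float
    age_mean: Optional[float]
    age_sd: Optional[float]
    age_median: Optional[float]
    age_iqr: Optional[tuple[float, float]]
    age_range: Optional[tuple[float, float]]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.age_iqr is not None:
            d["age_iqr"] = list(self.age_iqr)
        if self.age_range is not None:
            d["age_range"] = list(self.age_range)
        return d


def summarize_cohort(
    patients: Sequence[PatientRecord],
    encounters: Sequence[EncounterRecord],
    n_samples: int = 0,
) -> CohortSummary:
    """Tabulate demographics of a cohort the way clinical papers report them.

    Age is computed at each patient's first cohort encounter start; a
    patient counts once. Mortality counts patients with any in-hospital
    death signal. Deterministic and permutation-invariant in input order.
    """
    by_patient: dict[str, PatientRecord] = {p.patient_id: p for p in patients}
    first_start: dict[str, dt.datetime] = {}
    died: set[str] = set()
    for enc in sorted(encounters, key=lambda e: (e.patient_id, e.start)):
        first_start.setdefault(enc.patient_id, enc.start)
        patient = by_patient.get(enc.patient_id)
        death_in_window = (
            patient is not None
            and patient.deceased_datetime is not None
            and enc.end is not None
            and enc.start <= patient.deceased_datetime <= enc.end
        )
        if enc.died_in_encounter or death_in_window:
            died.add(enc.patient_id)

    cohort_patients = [by_patient[pid] for pid in sorted(first_start) if pid in by_patient]
    ages: list[int] = []
    band_counts = {band: 0 for band in AGE_BANDS}
    age_unknown = 0
    sex_counts = {s.value: 0 for s in Sex}
    insurance_counts = {i.value: 0 for i in Insurance}
    for patient in cohort_patients:
        sex_counts[patient.sex.value] += 1
        insurance_counts[patient.insurance.value] += 1
        if patient.birth_date is None:
            age_unknown += 1
            continue
        age = floored_age_years(patient.birth_date, first_start[patient.patient_id])
        ages.append(age)
        band_counts[age_band(age)] += 1

    n = len(cohort_patients)
    if ages:
        quartiles = statistics.quantiles(ages, n=4) if len(ages) >= 2 else [ages[0]] * 3
        summary_stats = dict(
            age_mean=statistics.fmean(ages),
            age_sd=statistics.stdev(ages) if len(ages) >= 2 else 0.0,
            age_median=float(statistics.median(ages)),
            age_iqr=(quartiles[0], quartiles[2]),
            age_range=(float(min(ages)), float(max(ages))),
        )
    else:
        summary_stats = dict(age_mean=None, age_sd=None, age_median=None,
                             age_iqr=None, age_range=None)
    return CohortSummary(
        n_patients=n,
        n_samples=n_samples,
        age_band_counts=band_counts,
        age_unknown=age_unknown,
        sex_counts=sex_counts,
        insurance_counts=insurance_counts,
        mortality_count=len(died),
        mortality_rate=(len(died) / n) if n else 0.0,
        **summary_stats,
    )
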