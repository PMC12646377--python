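"""Read FHIR R4 resources into typed records; write RiskAssessment back out.

Two transport dialects are accepted and auto-detected: a single Bundle JSON
object, or NDJSON with one resource per line (bulk-export flavor). Each of
the ten supported resource types has a dedicated build function that applies
that type's timestamp and code/text extraction rules. Unsupported types and
malformed entries are counted and logged, never fatal.

Timestamp source per type (earliest clinically meaningful instant, with a
deterministic fallback chain):

==================  =====================================================
Encounter           period.start
Condition           recordedDate, else onsetDateTime
Observation         effectiveDateTime, else issued
Procedure           performedDateTime, else performedPeriod.start
ImagingStudy        started
DiagnosticReport    effectiveDateTime, else issued
ServiceRequest      authoredOn
EpisodeOfCare       period.start
Medication family   effectiveDateTime/effectivePeriod.start, else
                    dateAsserted (Statement), else authoredOn (Request)
==================  =====================================================

Events with no resolvable timestamp cannot be windowed safely and are
skipped with a warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import urllib.error
import urllib.request
from pathlib import Path
from typing import Iterable, Optional, Union

from ._time import parse_datetime, to_fhir_instant
from .types import (
    EVENT_RESOURCE_TYPES,
    RESOURCE_TYPE_ALIASES,
    ClinicalEvent,
    Coding,
    EncounterRecord,
    Insurance,
    PatientRecord,
    RiskAssessmentRecord,
    Sex,
    Task,
)

logger = logging.getLogger(__name__)

#: Coverage type codes mapped onto the three-valued insurance enum;
#: anything unmapped falls through to "unknown".
DEFAULT_INSURANCE_CODE_TABLE = {
    "GKV": Insurance.STATUTORY,
    "gesetzlich": Insurance.STATUTORY,
    "statutory": Insurance.STATUTORY,
    "PUBLICPOL": Insurance.STATUTORY,
    "PKV": Insurance.PRIVATE,
    "privat": Insurance.PRIVATE,
    "private": Insurance.PRIVATE,
}

#: Discharge-disposition codes interpreted as in-hospital death.
DEATH_DISPOSITION_CODES = frozenset({"exp", "dead", "07", "tod"})

#: Coding system used to tag the diagnosis role (main diagnosis detection).
DIAGNOSIS_ROLE_SYSTEM = "http://terminology.hl7.org/CodeSystem/diagnosis-role"


class ConfigurationError(ValueError):
    """A request referenced an unknown resource type or invalid setting."""


@dataclasses.dataclass
class ParseResult:
    patients: list[PatientRecord]
    encounters: list[EncounterRecord]
    events: list[ClinicalEvent]
    skipped: int = 0

    def __iter__(self):
        return iter((self.patients, self.encounters, self.events, self.skipped))


def _strip_reference(ref: Optional[str]) -> Optional[str]:
    """'Patient/p1' -> 'p1'; 'urn:uuid:x' -> 'x'; bare ids pass through."""
    if not ref:
        return None
    if ref.startswith("urn:uuid:"):
        return ref[len("urn:uuid:"):]
    return ref.rsplit("/", 1)[-1]


def _codings(codeable: Optional[dict]) -> tuple[Coding, ...]:
    if not codeable:
        return ()
    out = []
    for coding in codeable.get("coding", []):
        code = coding.get("code")
        if code:
            out.append(Coding(coding.get("system"), code, coding.get("display")))
    if not out and codeable.get("text"):
        out.append(Coding(None, codeable["text"]))
    return tuple(out)


# --------------------------------------------------------------------------
# per-type build functions


def _build_patient(res: dict) -> PatientRecord:
    sex = {"female": Sex.FEMALE, "male": Sex.MALE}.get(res.get("gender"), Sex.UNKNOWN)
    birth = parse_datetime(res.get("birthDate"))
    return PatientRecord(
        patient_id=res["id"],
        birth_date=birth.date() if birth else None,
        sex=sex,
        deceased_datetime=parse_datetime(res.get("deceasedDateTime")),
    )


def _build_encounter(res: dict) -> Optional[EncounterRecord]:
    period = res.get("period", {})
    start = parse_datetime(period.get("start"))
    if start is None:
        return None
    patient_id = _strip_reference((res.get("subject") or {}).get("reference"))
    if not patient_id:
        return None
    klass = res.get("class") or {}
    disposition = None
    hosp = res.get("hospitalization") or {}
    for coding in (hosp.get("dischargeDisposition") or {}).get("coding", []):
        if coding.get("code"):
            disposition = coding["code"]
            break
    return EncounterRecord(
        encounter_id=res["id"],
        patient_id=patient_id,
        start=start,
        end=parse_datetime(period.get("end")),
        encounter_class=klass.get("code"),
        discharge_disposition=disposition,
        died_in_encounter=disposition in DEATH_DISPOSITION_CODES,
    )


def _event_common(res: dict, timestamp, codes=(), value_text=None, value_quantity=None,
                  resource_type=None) -> Optional[ClinicalEvent]:
    if timestamp is None:
        logger.warning("%s/%s has no resolvable timestamp; skipped",
                       res.get("resourceType"), res.get("id"))
        return None
    subject = res.get("subject") or res.get("patient") or {}
    patient_id = _strip_reference(subject.get("reference"))
    if not patient_id:
        return None
    encounter_ref = res.get("encounter") or res.get("context") or {}
    return ClinicalEvent(
        event_id=res["id"],
        patient_id=patient_id,
        resource_type=resource_type or res["resourceType"],
        timestamp=timestamp,
        encounter_id=_strip_reference(encounter_ref.get("reference")),
        codes=tuple(codes),
        value_text=value_text,
        value_quantity=value_quantity,
    )


def _build_condition(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime(res.get("recordedDate")) or parse_datetime(res.get("onsetDateTime"))
    codes = list(_codings(res.get("code")))
    # Diagnosis-role codings (eg a "hauptdiagnose" tag) ride along after the
    # primary code so cohort rules can detect the main diagnosis.
    for category in res.get("category", []):
        for coding in category.get("coding", []):
            if coding.get("code"):
                codes.append(Coding(coding.get("system"), coding["code"],
                                    coding.get("display")))
    return _event_common(res, ts, codes)


def _build_observation(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime(res.get("effectiveDateTime")) or parse_datetime(res.get("issued"))
    quantity = None
    vq = res.get("valueQuantity")
    if vq and vq.get("value") is not None:
        quantity = (float(vq["value"]), vq.get("unit"))
    return _event_common(res, ts, _codings(res.get("code")),
                         value_text=res.get("valueString"), value_quantity=quantity)


def _build_procedure(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime(res.get("performedDateTime"))
    if ts is None:
        ts = parse_datetime((res.get("performedPeriod") or {}).get("start"))
    return _event_common(res, ts, _codings(res.get("code")))


def _build_imaging_study(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime(res.get("started"))
    # One event per study; modality codes of all series, deduplicated.
    seen, codes = set(), []
    for series in res.get("series", []):
        modality = series.get("modality") or {}
        code = modality.get("code")
        if code and code not in seen:
            seen.add(code)
            codes.append(Coding(modality.get("system"), code, modality.get("display")))
    return _event_common(res, ts, codes)


def _build_diagnostic_report(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime(res.get("effectiveDateTime")) or parse_datetime(res.get("issued"))
    return _event_common(res, ts, _codings(res.get("code")),
                         value_text=res.get("conclusion"))


def _build_service_request(res: dict) -> Optional[ClinicalEvent]:
    return _event_common(res, parse_datetime(res.get("authoredOn")),
                         _codings(res.get("code")))


def _build_episode_of_care(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime((res.get("period") or {}).get("start"))
    codes = []
    for t in res.get("type", []):
        codes.extend(_codings(t))
    return _event_common(res, ts, codes, resource_type="EpisodeOfCare")


def _build_medication(res: dict) -> Optional[ClinicalEvent]:
    ts = parse_datetime(res.get("effectiveDateTime"))
    if ts is None:
        ts = parse_datetime((res.get("effectivePeriod") or {}).get("start"))
    if ts is None:
        ts = parse_datetime(res.get("dateAsserted")) or parse_datetime(res.get("authoredOn"))
    return _event_common(res, ts, _codings(res.get("medicationCodeableConcept")),
                         resource_type="Medication")


_EVENT_BUILDERS = {
    "Condition": _build_condition,
    "Observation": _build_observation,
    "Procedure": _build_procedure,
    "ImagingStudy": _build_imaging_study,
    "DiagnosticReport": _build_diagnostic_report,
    "ServiceRequest": _build_service_request,
    "EpisodeOfCare": _build_episode_of_care,
    "MedicationStatement": _build_medication,
    "MedicationAdministration": _build_medication,
    "MedicationRequest": _build_medication,
}


# --------------------------------------------------------------------------
# stream parsing


def _iter_resources(source: Union[str, bytes, Path, Iterable[dict]]) -> Iterable[dict]:
    """Yield resource dicts from a Bundle object, NDJSON text, path, or dicts."""
    if isinstance(source, Path):
        source = source.read_text()
    elif isinstance(source, bytes):
        source = source.decode("utf-8")
    if not isinstance(source, str):
        for res in source:
            yield res
        return
    text = source.strip()
    if not text:
        return
    try:
        obj = json.loads(text)
    except json.JSONDecodeError:
        obj = None
    if isinstance(obj, dict):
        if obj.get("resourceType") == "Bundle":
            for entry in obj.get("entry", []):
                if isinstance(entry.get("resource"), dict):
                    yield entry["resource"]
                else:
                    yield entry  # malformed entry: counted by the caller
        else:
            yield obj
        return
    # NDJSON: one resource per line
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            yield json.loads(line)
        except json.JSONDecodeError:
            yield {"__malformed_line__": lineno}


def parse_resources(
    source: Union[str, bytes, Path, Iterable[dict]],
    insurance_code_table: Optional[dict] = None,
) -> ParseResult:
    """Parse a FHIR R4 stream into typed records.

    Every supported resource yields exactly one record/event; unsupported
    resource types and malformed entries are counted in ``skipped`` and
    logged. Coverage resources are consumed to set patient insurance (they
    are helpers, not events). References are normalized to bare ids.
    """
    table = dict(DEFAULT_INSURANCE_CODE_TABLE if insurance_code_table is None
                 else insurance_code_table)
    patients: dict[str, PatientRecord] = {}
    encounters: list[EncounterRecord] = []
    events: list[ClinicalEvent] = []
    coverages: list[tuple[str, Insurance]] = []
    skipped = 0

    for res in _iter_resources(source):
        if not isinstance(res, dict) or "__malformed_line__" in res or "resourceType" not in res:
            skipped += 1
            logger.warning("malformed entry skipped")
            continue
        rtype = res["resourceType"]
        if rtype == "Coverage":
            beneficiary = _strip_reference((res.get("beneficiary") or {}).get("reference"))
            insurance = Insurance.UNKNOWN
            for coding in (res.get("type") or {}).get("coding", []):
                if coding.get("code") in table:
                    insurance = table[coding["code"]]
                    break
            if beneficiary:
                coverages.append((beneficiary, insurance))
            continue
        if rtype not in ("Patient", "Encounter") and rtype not in _EVENT_BUILDERS:
            skipped += 1
            logger.warning("unsupported resourceType %s skipped", rtype)
            continue
        if not res.get("id"):
            skipped += 1
            logger.warning("%s without mandatory id skipped", rtype)
            continue
        if rtype == "Patient":
            record = _build_patient(res)
            patients[record.patient_id] = record
        elif rtype == "Encounter":
            enc = _build_encounter(res)
            if enc is None:
                skipped += 1
                logger.warning("Encounter/%s missing period.start or subject; skipped",
                               res["id"])
            else:
                encounters.append(enc)
        else:
            event = _EVENT_BUILDERS[rtype](res)
            if event is None:
                skipped += 1
            else:
                events.append(event)

    for beneficiary, insurance in coverages:
        if beneficiary in patients:
            patients[beneficiary].insurance = insurance
    return ParseResult(list(patients.values()), encounters, events, skipped)


def extract_events(
    source: Union[str, bytes, Path, Iterable[dict]],
    resource_type: str,
) -> list[ClinicalEvent]:
    """Extract events of one supported type, sorted by timestamp ascending."""
    canonical = RESOURCE_TYPE_ALIASES.get(resource_type, resource_type)
    if canonical not in EVENT_RESOURCE_TYPES:
        raise ConfigurationError(
            f"unknown or non-event resource type {resource_type!r}; "
            f"supported: {EVENT_RESOURCE_TYPES}"
        )
    result = parse_resources(source)
    selected = [e for e in result.events if e.resource_type == canonical]
    selected.sort(key=lambda e: (e.timestamp, e.event_id))
    return selected


def merge_encounters(encounters: list[EncounterRecord]) -> list[EncounterRecord]:
    """Collapse overlapping encounters of one patient into single stays.

    A hospital-internal transfer shows up as back-to-back Encounter
    resources; merging (min start, max end) prevents it from counting as a
    readmission downstream. Ongoing encounters (no end) absorb everything
    starting after them.
    """
    by_patient: dict[str, list[EncounterRecord]] = {}
    for enc in encounters:
        by_patient.setdefault(enc.patient_id, []).append(enc)
    merged_all: list[EncounterRecord] = []
    for patient_id in sorted(by_patient):
        stays = sorted(by_patient[patient_id], key=lambda e: (e.start, e.encounter_id))
        current = None
        for enc in stays:
            if current is None:
                current = dataclasses.replace(enc)
                continue
            overlaps = current.end is None or enc.start <= current.end
            if overlaps:
                if current.end is not None and (enc.end is None or enc.end > current.end):
                    current.end = enc.end
                current.died_in_encounter = current.died_in_encounter or enc.died_in_encounter
                if enc.discharge_disposition:
                    current.discharge_disposition = enc.discharge_disposition
                current.merged_ids = current.merged_ids + (enc.encounter_id,)
            else:
                merged_all.append(current)
                current = dataclasses.replace(enc)
        if current is not None:
            merged_all.append(current)
    return merged_all


# --------------------------------------------------------------------------
# RiskAssessment output


def write_riskassessment(record: RiskAssessmentRecord) -> dict:
    """Render a prediction as an R4 RiskAssessment JSON object.

    The emitted resource re-parses under :func:`parse_riskassessment`
    (round trip on all record fields).
    """
    if not (0.0 <= record.probability <= 1.0):
        raise ValueError(f"probability {record.probability} outside [0, 1]")
    resource: dict = {
        "resourceType": "RiskAssessment",
        "status": "final",
        "subject": {"reference": f"Patient/{record.subject}"},
        "occurrenceDateTime": to_fhir_instant(record.occurrence),
        "method": {"text": record.task.value},
        "note": [{"text": f"model_version={record.model_version}"}],
        "prediction": [
            {
                "outcome": {"text": record.outcome_code},
                "probabilityDecimal": record.probability,
            }
        ],
    }
    if record.assessment_id:
        resource["id"] = record.assessment_id
    if record.encounter:
        resource["encounter"] = {"reference": f"Encounter/{record.encounter}"}
    if record.basis:
        resource["basis"] = [{"reference": ref} for ref in record.basis]
    return resource


def parse_riskassessment(resource: dict) -> RiskAssessmentRecord:
    """Inverse of :func:`write_riskassessment`."""
    if resource.get("resourceType") != "RiskAssessment":
        raise ValueError("not a RiskAssessment resource")
    prediction = resource["prediction"][0]
    note = (resource.get("note") or [{}])[0].get("text", "")
    model_version = note.split("model_version=", 1)[-1] if note else ""
    encounter = _strip_reference((resource.get("encounter") or {}).get("reference"))
    occurrence = parse_datetime(resource["occurrenceDateTime"])
    if occurrence is None:
        raise ValueError("RiskAssessment without parseable occurrenceDateTime")
    return RiskAssessmentRecord(
        subject=_strip_reference(resource["subject"]["reference"]) or "",
        task=Task(resource.get("method", {}).get("text", "readmission")),
        probability=float(prediction["probabilityDecimal"]),
        outcome_code=prediction.get("outcome", {}).get("text", "positive"),
        occurrence=occurrence,
        model_version=model_version,
        encounter=encounter,
        basis=tuple(_strip_reference(b.get("reference")) or ""
                    for b in resource.get("basis", [])),
        assessment_id=resource.get("id"),
    )


@dataclasses.dataclass
class PushStatus:
    resource_id: Optional[str]
    resource_type: str
    status_code: Optional[int]
    ok: bool
    error: Optional[str] = None


def push_resources(
    resources: list[dict],
    endpoint: str,
    auth_token: Optional[str] = None,
    timeout: float = 10.0,
) -> list[PushStatus]:
    """POST (or PUT, when the resource carries an id) each resource to a
    FHIR endpoint. Failures are reported per resource, never dropped."""
    statuses: list[PushStatus] = []
    for resource in resources:
        rtype = resource.get("resourceType", "Resource")
        rid = resource.get("id")
        url = f"{endpoint.rstrip('/')}/{rtype}" + (f"/{rid}" if rid else "")
        body = json.dumps(resource).encode("utf-8")
        req = urllib.request.Request(
            url, data=body, method="PUT" if rid else "POST",
            headers={"Content-Type": "application/fhir+json"},
        )
        if auth_token:
            req.add_header("Authorization", f"Bearer {auth_token}")
        try:
            with urllib.request.urlopen(req, timeout=timeout) as resp:
                statuses.append(PushStatus(rid, rtype, resp.status,
                                           200 <= resp.status < 300))
        except urllib.error.HTTPError as exc:
            statuses.append(PushStatus(rid, rtype, exc.code, False, str(exc)))
        except (urllib.error.URLError, OSError) as exc:
            statuses.append(PushStatus(rid, rtype, None, False, str(exc)))
    return statuses
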