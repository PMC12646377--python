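"""Seeded synthetic FHIR R4 populations with planted, configurable effects.

The generator emulates multi-encounter inpatient histories — per-day
Observations, Medications, Procedures, DiagnosticReports with templated
free-text conclusions, ICD-coded Conditions (including a tagged main
diagnosis), ImagingStudy series with DICOM modalities, ServiceRequests,
EpisodeOfCare spells, Coverage-derived insurance, and in-hospital deaths —
and plants outcome effects of configurable strength:

* readmission — a stay whose record carries ``risk_condition_code`` (the
  patient carries the risk diagnosis at that admission, recorded with
  probability ``p_risk_condition`` per stay) is followed by a readmission
  within 30 days of discharge with probability ``p_readmit_given_risk``,
  other stays with ``p_readmit_baseline``. Every patient has at least two
  completed stays and the number of stays is drawn independently of the
  readmission coins, so the cohort rule ("multiple stays") selects no
  label information; inter-stay gaps realize the coins (<30 d vs >=40 d),
  and a positive coin on the final completed stay is realized as an
  ongoing readmission encounter (admitted, not yet discharged) that the
  labeler sees but the sampler never emits. Deceased patients are not
  readmitted after death;
* mortality — death probability rises linearly with age above 60; deaths
  occur in the final stay and set both the patient's deceasedDateTime and a
  death discharge disposition;
* imaging — a ServiceRequest marker authored at admission raises the
  probability of a matching-modality study within the first 24 hours to
  ``imaging_signal_strength`` (vs ``imaging_noise`` without it);
* icd — conditions coded after the first day are foreshadowed by an early
  DiagnosticReport conclusion that names the code category, with
  probability ``icd_signal_strength``.

Same (config, seed) yields byte-identical output. A ground-truth table
lists every encounter's true label per task, derived from the generated
timeline by construction (independently of the pipeline's labeling code).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from typing import Optional

import numpy as np
import pandas as pd

from ._time import UTC, to_fhir_instant

#: Embedded ICD-10-GM-style vocabulary (~50 codes); no external download.
ICD_VOCABULARY = (
    ("A41.9", "Sepsis, unspecified organism"),
    ("B96.2", "Escherichia coli as cause of disease"),
    ("C18.9", "Malignant neoplasm of colon"),
    ("C34.9", "Malignant neoplasm of bronchus or lung"),
    ("C50.9", "Malignant neoplasm of breast"),
    ("D64.9", "Anaemia, unspecified"),
    ("E03.9", "Hypothyroidism, unspecified"),
    ("E11.9", "Type 2 diabetes mellitus without complications"),
    ("E66.0", "Obesity due to excess calories"),
    ("E78.0", "Pure hypercholesterolaemia"),
    ("E86", "Volume depletion"),
    ("E87.6", "Hypokalaemia"),
    ("F05.9", "Delirium, unspecified"),
    ("F10.2", "Alcohol dependence syndrome"),
    ("F32.9", "Depressive episode, unspecified"),
    ("G40.9", "Epilepsy, unspecified"),
    ("G45.9", "Transient cerebral ischaemic attack"),
    ("G62.9", "Polyneuropathy, unspecified"),
    ("I10.0", "Essential hypertension"),
    ("I20.0", "Unstable angina"),
    ("I21.4", "Acute subendocardial myocardial infarction"),
    ("I25.1", "Atherosclerotic heart disease"),
    ("I35.0", "Aortic valve stenosis"),
    ("I48.1", "Persistent atrial fibrillation"),
    ("I44.2", "Atrioventricular block, complete"),
    ("I63.9", "Cerebral infarction, unspecified"),
    ("I80.2", "Thrombosis of deep vessels of lower extremity"),
    ("J15.9", "Bacterial pneumonia, unspecified"),
    ("J18.9", "Pneumonia, unspecified"),
    ("J44.1", "COPD with acute exacerbation"),
    ("J90", "Pleural effusion"),
    ("J96.0", "Acute respiratory failure"),
    ("K29.7", "Gastritis, unspecified"),
    ("K57.3", "Diverticular disease of large intestine"),
    ("K70.3", "Alcoholic cirrhosis of liver"),
    ("K80.2", "Calculus of gallbladder"),
    ("K92.2", "Gastrointestinal haemorrhage"),
    ("L03.1", "Cellulitis of other parts of limb"),
    ("M17.9", "Gonarthrosis, unspecified"),
    ("M54.5", "Low back pain"),
    ("N17.9", "Acute kidney failure, unspecified"),
    ("N18.3", "Chronic kidney disease, stage 3"),
    ("N39.0", "Urinary tract infection"),
    ("R07.4", "Chest pain, unspecified"),
    ("R26.8", "Abnormalities of gait and mobility"),
    ("R55", "Syncope and collapse"),
    ("R57.0", "Cardiogenic shock"),
    ("S06.0", "Concussion"),
    ("S72.0", "Fracture of neck of femur"),
    ("Z51.1", "Chemotherapy session for neoplasm"),
)

ICD_SYSTEM = "http://fhir.de/CodeSystem/dimdi/icd-10-gm"
DICOM_MODALITY_SYSTEM = "http://dicom.nema.org/resources/ontology/DCM"
DIAGNOSIS_ROLE_SYSTEM = "http://terminology.hl7.org/CodeSystem/diagnosis-role"

LAB_CODES = (
    ("718-7", "Hemoglobin", "g/dL", 8.0, 17.0),
    ("2345-7", "Glucose", "mmol/L", 3.5, 12.0),
    ("2160-0", "Creatinine", "mg/dL", 0.5, 3.0),
    ("1988-5", "C reactive protein", "mg/L", 0.0, 120.0),
    ("6690-2", "Leukocytes", "10*9/L", 3.0, 18.0),
    ("2823-3", "Potassium", "mmol/L", 3.0, 5.5),
)

MEDICATION_CODES = (
    ("B01AC06", "acetylsalicylic acid"),
    ("C03CA01", "furosemide"),
    ("C07AB07", "bisoprolol"),
    ("C09AA05", "ramipril"),
    ("A10BA02", "metformin"),
    ("N02BE01", "paracetamol"),
    ("J01CR02", "amoxicillin and beta-lactamase inhibitor"),
    ("B05BB01", "electrolyte solution"),
)

PROCEDURE_CODES = (
    ("1-632", "Oesophagogastroduodenoscopy"),
    ("8-930", "Monitoring of respiration, heart and circulation"),
    ("3-200", "Native computed tomography of skull"),
    ("8-800", "Transfusion of whole blood"),
    ("1-440", "Endoscopic biopsy of upper digestive tract"),
    ("5-469", "Other operations on intestine"),
)

REPORT_TEMPLATES = (
    "Clinical course stable, routine monitoring continued.",
    "No acute distress noted on ward round, vitals within limits.",
    "Follow-up examination recommended, findings unchanged.",
    "Mild improvement of presenting symptoms under current therapy.",
)

IMAGING_MODALITIES = ("CT", "MR")
NOISE_MODALITIES = ("US", "CR")


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the generated population."""

    n_patients: int = 2000
    seed: int = 0
    # readmission effect
    p_risk_condition: float = 0.5
    risk_condition_code: str = "I50.9"
    risk_condition_display: str = "Acute decompensated heart failure"
    p_readmit_given_risk: float = 0.9
    p_readmit_baseline: float = 0.1
    p_extra_stay: float = 0.3  # chance of each stay beyond the guaranteed two
    max_stays: int = 8
    # stays
    min_stay_days: int = 1
    max_stay_days: int = 9
    # mortality effect
    mortality_base: float = 0.01
    mortality_age_slope: float = 0.004  # per year above age 60
    # imaging effect
    p_imaging_marker: float = 0.35
    imaging_signal_strength: float = 0.9
    imaging_noise: float = 0.05
    # icd effect
    icd_mean_codes: float = 1.5
    icd_signal_strength: float = 0.9
    # per-day event rates
    obs_per_day: float = 1.0
    med_per_day: float = 0.4
    proc_per_day: float = 0.25
    report_per_day: float = 0.4
    start_year: int = 2021

    def __post_init__(self) -> None:
        probs = (self.p_risk_condition, self.p_readmit_given_risk,
                 self.p_readmit_baseline, self.p_extra_stay,
                 self.p_imaging_marker, self.imaging_signal_strength,
                 self.imaging_noise, self.icd_signal_strength)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_readmit_given_risk < self.p_readmit_baseline:
            raise ValueError("p_readmit_given_risk must be >= p_readmit_baseline")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not (1 <= self.min_stay_days <= self.max_stay_days):
            raise ValueError("invalid stay length bounds")
        for rate in (self.obs_per_day, self.med_per_day, self.proc_per_day,
                     self.report_per_day, self.icd_mean_codes):
            if rate < 0:
                raise ValueError("event rates must be >= 0")


@dataclasses.dataclass
class Population:
    resources: list[dict]
    truth: pd.DataFrame

    def to_ndjson(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True) for r in self.resources)


def _fmt(ts: dt.datetime) -> str:
    return to_fhir_instant(ts)


class _Generator:
    def __init__(self, config: SyntheticConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.resources: list[dict] = []
        self.truth_rows: list[dict] = []
        self._event_counter = 0

    def _eid(self) -> str:
        self._event_counter += 1
        return f"e{self._event_counter}"

    def run(self) -> Population:
        for i in range(self.cfg.n_patients):
            self._patient(i)
        truth = pd.DataFrame(
            self.truth_rows,
            columns=["patient_id", "encounter_id", "risk_carrier",
                     "readmission", "mortality", "imaging", "icd"],
        )
        return Population(self.resources, truth)

    # ------------------------------------------------------------------
    def _patient(self, i: int) -> None:
        cfg, rng = self.cfg, self.rng
        pid = f"p{i:05d}"
        age = int(rng.integers(0, 95))
        sex = rng.choice(["female", "male", "unknown"], p=[0.50, 0.48, 0.02])
        insurance = rng.choice(["GKV", "PKV", "UNK"], p=[0.75, 0.07, 0.18])

        first_start = dt.datetime(cfg.start_year, 1, 1, tzinfo=UTC) + dt.timedelta(
            days=int(rng.integers(0, 365)), hours=int(rng.integers(6, 20)))
        birth_date = (first_start - dt.timedelta(days=int(age * 365.25 + rng.integers(10, 300)))).date()

        # number of completed stays is drawn before any readmission coin, so
        # chain length (and hence history size) carries no label information
        n_stays = 2
        while n_stays < cfg.max_stays and rng.random() < cfg.p_extra_stay:
            n_stays += 1

        p_death = min(0.6, cfg.mortality_base
                      + cfg.mortality_age_slope * max(age - 60, 0))
        dies = bool(rng.random() < p_death)

        # each stay records the risk condition independently and draws its
        # 30-day readmission coin at p1/p0; the coin is realized as the gap
        # to the next stay (< 30 d vs >= 40 d), or, on the final completed
        # stay, as an ongoing readmission encounter with no discharge yet
        stays: list[tuple[dt.datetime, dt.datetime, bool]] = []
        coins: list[bool] = []
        start = first_start
        for j in range(n_stays):
            days = int(rng.integers(cfg.min_stay_days, cfg.max_stay_days + 1))
            end = start + dt.timedelta(days=days)
            risk = bool(rng.random() < cfg.p_risk_condition)
            p_readmit = (cfg.p_readmit_given_risk if risk
                         else cfg.p_readmit_baseline)
            coin = bool(rng.random() < p_readmit)
            if j == n_stays - 1 and dies:
                coin = False  # no readmission after in-hospital death
            stays.append((start, end, risk))
            coins.append(coin)
            if coin:
                gap = dt.timedelta(days=int(rng.integers(1, 30)),
                                   hours=int(rng.integers(0, 24)))
            else:
                gap = dt.timedelta(days=int(rng.integers(40, 201)),
                                   hours=int(rng.integers(0, 12)))
            start = end + gap
        ongoing_start = start if coins[-1] else None
        if not coins[-1] and rng.random() < 0.1:
            # occasionally export catches an unrelated ongoing admission
            ongoing_start = stays[-1][1] + dt.timedelta(
                days=int(rng.integers(40, 201)))

        deceased_at = stays[-1][1] - dt.timedelta(hours=1) if dies else None

        patient_resource = {
            "resourceType": "Patient", "id": pid, "gender": str(sex),
            "birthDate": birth_date.isoformat(),
        }
        if deceased_at is not None:
            patient_resource["deceasedDateTime"] = _fmt(deceased_at)
        self.resources.append(patient_resource)
        self.resources.append({
            "resourceType": "Coverage", "id": f"cov-{pid}",
            "beneficiary": {"reference": f"Patient/{pid}"},
            "type": {"coding": [{"system": "http://fhir.de/CodeSystem/versicherungsart-de-basis",
                                 "code": str(insurance)}]},
        })
        self.resources.append({
            "resourceType": "EpisodeOfCare", "id": f"eoc-{pid}",
            "patient": {"reference": f"Patient/{pid}"},
            "period": {"start": _fmt(first_start)},
            "type": [{"coding": [{"code": "inpatient-spell",
                                  "display": "inpatient care episode"}]}],
        })

        for j, (s, e, risk) in enumerate(stays):
            last = j == len(stays) - 1
            died_here = dies and last
            next_start = ongoing_start if last else stays[j + 1][0]
            readmitted = (next_start is not None
                          and next_start <= e + dt.timedelta(days=30))
            self._encounter(pid, f"{pid}-s{j}", s, e, died_here, readmitted,
                            risk, birth_date)
        if ongoing_start is not None:
            # admitted at export time: visible to the labeler, never a sample
            self.resources.append({
                "resourceType": "Encounter", "id": f"{pid}-ongoing",
                "subject": {"reference": f"Patient/{pid}"},
                "period": {"start": _fmt(ongoing_start)},
                "class": {"code": "IMP"},
            })

    # ------------------------------------------------------------------
    def _encounter(self, pid: str, eid: str, start: dt.datetime,
                   end: dt.datetime, died: bool, readmitted: bool,
                   risk: bool, birth_date: dt.date) -> None:
        cfg, rng = self.cfg, self.rng
        days = max(1, int((end - start).total_seconds() // 86400))
        disposition = "exp" if died else "home"
        self.resources.append({
            "resourceType": "Encounter", "id": eid,
            "subject": {"reference": f"Patient/{pid}"},
            "period": {"start": _fmt(start), "end": _fmt(end)},
            "class": {"code": "IMP"},
            "hospitalization": {"dischargeDisposition": {
                "coding": [{"code": disposition}]}},
        })
        ref = {"reference": f"Encounter/{eid}"}
        subject = {"reference": f"Patient/{pid}"}

        # main diagnosis at admission + 2 h, tagged with a diagnosis-role code
        main_idx = int(rng.integers(0, len(ICD_VOCABULARY)))
        main_code, main_display = ICD_VOCABULARY[main_idx]
        self.resources.append({
            "resourceType": "Condition", "id": self._eid(),
            "subject": subject, "encounter": ref,
            "recordedDate": _fmt(start + dt.timedelta(hours=2)),
            "code": {"coding": [{"system": ICD_SYSTEM, "code": main_code,
                                 "display": main_display}]},
            "category": [{"coding": [{"system": DIAGNOSIS_ROLE_SYSTEM,
                                      "code": "hauptdiagnose",
                                      "display": "Hauptdiagnose"}]}],
        })
        if risk:
            self.resources.append({
                "resourceType": "Condition", "id": self._eid(),
                "subject": subject, "encounter": ref,
                "recordedDate": _fmt(start + dt.timedelta(hours=3)),
                "code": {"coding": [{"system": ICD_SYSTEM,
                                     "code": cfg.risk_condition_code,
                                     "display": cfg.risk_condition_display}]},
            })

        # --- imaging: markers at admission; studies in the first 24 h ---
        first24: list[str] = []
        for modality in IMAGING_MODALITIES:
            marker = rng.random() < cfg.p_imaging_marker
            if marker:
                self.resources.append({
                    "resourceType": "ServiceRequest", "id": self._eid(),
                    "subject": subject, "encounter": ref,
                    "authoredOn": _fmt(start),
                    "code": {"coding": [{"code": f"REQ-{modality}",
                                         "display": f"request {modality} imaging"}]},
                })
            p_study = cfg.imaging_signal_strength if marker else cfg.imaging_noise
            if rng.random() < p_study:
                first24.append(modality)
                self._imaging_study(subject, ref, modality,
                                    start + dt.timedelta(hours=int(rng.integers(1, 24))))
        for modality in NOISE_MODALITIES:
            if rng.random() < cfg.imaging_noise:
                first24.append(modality)
                self._imaging_study(subject, ref, modality,
                                    start + dt.timedelta(hours=int(rng.integers(1, 24))))
        # late imaging past the 24 h label window
        if days >= 2 and rng.random() < 0.2:
            modality = str(rng.choice(IMAGING_MODALITIES + NOISE_MODALITIES))
            self._imaging_study(subject, ref, modality,
                                start + dt.timedelta(hours=int(rng.integers(25, 24 * days))))

        # --- icd: late conditions, foreshadowed by an early report ---
        icd_truth: set[str] = set()
        if days >= 2:
            n_codes = int(rng.poisson(cfg.icd_mean_codes))
            for _ in range(n_codes):
                code, display = ICD_VOCABULARY[int(rng.integers(0, len(ICD_VOCABULARY)))]
                hour = int(rng.integers(25, 24 * days + 1))
                icd_truth.add(code.split(".")[0][:3])
                self.resources.append({
                    "resourceType": "Condition", "id": self._eid(),
                    "subject": subject, "encounter": ref,
                    "recordedDate": _fmt(start + dt.timedelta(hours=hour)),
                    "code": {"coding": [{"system": ICD_SYSTEM, "code": code,
                                         "display": display}]},
                })
                if rng.random() < cfg.icd_signal_strength:
                    category = code.split(".")[0][:3]
                    self.resources.append({
                        "resourceType": "DiagnosticReport", "id": self._eid(),
                        "subject": subject, "encounter": ref,
                        "effectiveDateTime": _fmt(start + dt.timedelta(
                            hours=int(rng.integers(2, 21)))),
                        "code": {"coding": [{"code": "ADM", "display": "admission workup"}]},
                        "conclusion": (f"Initial workup suggestive of {display} "
                                       f"(category {category})."),
                    })

        # --- per-day background noise events ---
        for day in range(days):
            base = start + dt.timedelta(days=day)
            for _ in range(int(rng.poisson(cfg.obs_per_day))):
                code, display, unit, lo, hi = LAB_CODES[int(rng.integers(0, len(LAB_CODES)))]
                self.resources.append({
                    "resourceType": "Observation", "id": self._eid(),
                    "subject": subject, "encounter": ref,
                    "effectiveDateTime": _fmt(base + dt.timedelta(
                        hours=int(rng.integers(0, 24)))),
                    "code": {"coding": [{"system": "http://loinc.org",
                                         "code": code, "display": display}]},
                    "valueQuantity": {"value": round(float(rng.uniform(lo, hi)), 2),
                                      "unit": unit},
                })
            for _ in range(int(rng.poisson(cfg.med_per_day))):
                code, display = MEDICATION_CODES[int(rng.integers(0, len(MEDICATION_CODES)))]
                self.resources.append({
                    "resourceType": "MedicationStatement", "id": self._eid(),
                    "subject": subject, "context": ref,
                    "effectiveDateTime": _fmt(base + dt.timedelta(
                        hours=int(rng.integers(0, 24)))),
                    "medicationCodeableConcept": {"coding": [
                        {"system": "http://www.whocc.no/atc", "code": code,
                         "display": display}]},
                })
            for _ in range(int(rng.poisson(cfg.proc_per_day))):
                code, display = PROCEDURE_CODES[int(rng.integers(0, len(PROCEDURE_CODES)))]
                self.resources.append({
                    "resourceType": "Procedure", "id": self._eid(),
                    "subject": subject, "encounter": ref,
                    "performedDateTime": _fmt(base + dt.timedelta(
                        hours=int(rng.integers(0, 24)))),
                    "code": {"coding": [{"code": code, "display": display}]},
                })
            for _ in range(int(rng.poisson(cfg.report_per_day))):
                self.resources.append({
                    "resourceType": "DiagnosticReport", "id": self._eid(),
                    "subject": subject, "encounter": ref,
                    "effectiveDateTime": _fmt(base + dt.timedelta(
                        hours=int(rng.integers(0, 24)))),
                    "code": {"coding": [{"code": "WARD", "display": "ward note"}]},
                    "conclusion": str(rng.choice(REPORT_TEMPLATES)),
                })

        self.truth_rows.append({
            "patient_id": pid, "encounter_id": eid, "risk_carrier": risk,
            "readmission": readmitted, "mortality": died,
            "imaging": ",".join(sorted(set(first24))),
            "icd": ",".join(sorted(icd_truth)),
        })

    def _imaging_study(self, subject: dict, encounter_ref: dict,
                       modality: str, started: dt.datetime) -> None:
        self.resources.append({
            "resourceType": "ImagingStudy", "id": self._eid(),
            "subject": subject, "encounter": encounter_ref,
            "started": _fmt(started),
            "series": [{"modality": {"system": DICOM_MODALITY_SYSTEM,
                                     "code": modality}}],
        })


def generate_population(config: Optional[SyntheticConfig] = None,
                        **overrides) -> Population:
    """Generate a seeded synthetic population.

    Returns the FHIR resources (NDJSON-ready dicts) and a ground-truth
    table with one row per encounter and the true label for each task.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    return _Generator(config).run()


def validate_against_pipeline(config: Optional[SyntheticConfig] = None,
                              **overrides) -> dict:
    """Run parse -> merge -> label end-to-end and cross-check pipeline labels
    against the generator's ground truth.

    Readmission and mortality labels are deterministic functions of the
    generated timeline, so their mismatch counts must be exactly 0; the
    imaging and icd label sets are checked the same way.
    """
    from . import fhir_io, labeling
    from .types import Task

    population = generate_population(config, **overrides)
    result = fhir_io.parse_resources(population.resources)
    merged = fhir_io.merge_encounters(result.encounters)
    patients = {p.patient_id: p for p in result.patients}
    by_patient: dict[str, list] = {}
    for enc in merged:
        by_patient.setdefault(enc.patient_id, []).append(enc)
    events_by_patient: dict[str, list] = {}
    for ev in result.events:
        events_by_patient.setdefault(ev.patient_id, []).append(ev)

    mismatches = {t.value: 0 for t in Task}
    by_key = {(row.patient_id, row.encounter_id): row
              for row in population.truth.itertuples()}
    n_checked = 0
    for enc in merged:
        truth = by_key.get((enc.patient_id, enc.encounter_id))
        if truth is None:
            continue
        n_checked += 1
        events = events_by_patient.get(enc.patient_id, [])
        readm = labeling.label_readmission(enc, by_patient[enc.patient_id])
        if bool(readm) != bool(truth.readmission):
            mismatches["readmission"] += 1
        mort = labeling.label_mortality(enc, patients[enc.patient_id])
        if bool(mort) != bool(truth.mortality):
            mismatches["mortality"] += 1
        imaging = labeling.label_imaging(enc, events)
        truth_imaging = frozenset(truth.imaging.split(",")) - {""}
        if imaging != truth_imaging:
            mismatches["imaging"] += 1
        icd = labeling.label_icd(enc, events)
        truth_icd = frozenset(truth.icd.split(",")) - {""}
        if icd != truth_icd:
            mismatches["icd"] += 1

    return {
        "n_patients": len(result.patients),
        "n_encounters": len(merged),
        "n_events": len(result.events),
        "n_checked": n_checked,
        "skipped": result.skipped,
        "mismatches": mismatches,
    }
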