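"""Turn model outputs into risk scores and FHIR R4 RiskAssessment records.

Risk scores live in [0, 1]: probabilities pass through with validation
(out-of-range is an error, never clamped), raw linear scores map through
the logistic function. Binary tasks yield one RiskAssessment per window;
multilabel tasks fan out to one per (window, label) for queryability, with
an optional single-resource mode and an optional minimum-probability
emission filter (default 0: emit everything).
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Sequence, Union

import numpy as np

from .fhir_io import write_riskassessment
from .types import RiskAssessmentRecord, SampleWindow, Task


def to_risk_score(raw: float, kind: str = "probability") -> float:
    """Validate a probability or map a linear score through the logistic."""
    value = float(raw)
    if not math.isfinite(value):
        raise ValueError(f"non-finite model output: {raw!r}")
    if kind == "probability":
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"probability {value} outside [0, 1]")
        return value
    if kind == "linear":
        return 1.0 / (1.0 + math.exp(-value))
    raise ValueError(f"unknown raw output kind {kind!r}")


def build_assessments(
    predictions: Union[Sequence[float], np.ndarray],
    windows: Sequence[SampleWindow],
    task: Task,
    model_version: str,
    now: dt.datetime,
    label_space: Sequence[str] = (),
    min_probability: float = 0.0,
    mode: str = "per_label",
) -> list[RiskAssessmentRecord]:
    """Align predictions to windows and build RiskAssessment records.

    Binary: ``predictions`` is a length-n vector, one record per window
    with outcome_code "positive". Multilabel: an (n, n_labels) matrix, one
    record per (window, label) above ``min_probability`` (per_label mode)
    or one record per (window, top label) in single mode.
    """
    task = Task(task)
    preds = np.asarray(predictions, dtype=float)
    if preds.ndim == 1:
        if len(preds) != len(windows):
            raise ValueError(
                f"alignment mismatch: {len(preds)} predictions vs "
                f"{len(windows)} windows "
                f"(first window {windows[0].window_id if windows else 'n/a'})"
            )
        records = []
        for window, p in zip(windows, preds):
            score = to_risk_score(p)
            if score < min_probability:
                continue
            records.append(RiskAssessmentRecord(
                subject=window.patient_id, encounter=window.encounter_id,
                task=task, probability=score, outcome_code="positive",
                occurrence=now, model_version=model_version,
                assessment_id=f"ra-{task.value}-{window.window_id}",
            ))
        return records

    if preds.ndim != 2:
        raise ValueError("predictions must be a vector or a matrix")
    if preds.shape[0] != len(windows):
        raise ValueError(
            f"alignment mismatch: {preds.shape[0]} prediction rows vs "
            f"{len(windows)} windows"
        )
    if preds.shape[1] != len(label_space):
        raise ValueError(
            f"alignment mismatch: {preds.shape[1]} prediction columns vs "
            f"{len(label_space)} labels"
        )
    records = []
    for i, window in enumerate(windows):
        if mode == "single":
            j = int(np.argmax(preds[i]))
            columns = [j]
        elif mode == "per_label":
            columns = range(len(label_space))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for j in columns:
            score = to_risk_score(float(preds[i, j]))
            if score < min_probability:
                continue
            records.append(RiskAssessmentRecord(
                subject=window.patient_id, encounter=window.encounter_id,
                task=task, probability=score, outcome_code=label_space[j],
                occurrence=now, model_version=model_version,
                assessment_id=f"ra-{task.value}-{window.window_id}-{label_space[j]}",
            ))
    return records


def assessments_to_ndjson(records: Sequence[RiskAssessmentRecord]) -> str:
    """Serialize records as NDJSON of R4 RiskAssessment resources."""
    import json

    return "\n".join(json.dumps(write_riskassessment(r), sort_keys=True)
                     for r in records)
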