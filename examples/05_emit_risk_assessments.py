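"""Deployment output: model predictions as FHIR R4 RiskAssessment NDJSON.

Trains a small mortality model, scores every window, converts the
probabilities to risk scores, and renders them as RiskAssessment
resources — the same shape a hospital FHIR server would store as an audit
trail of predictions.
"""

import datetime as dt
import json

from fhirpipe import (
    BackendSpec,
    LabelKind,
    PipelineConfig,
    SyntheticConfig,
    Task,
    build_assessments,
    fit_and_score,
    generate_population,
    parse_resources,
    parse_riskassessment,
    write_riskassessment,
)
from fhirpipe.pipeline import materialize, prepare

parsed = parse_resources(
    generate_population(SyntheticConfig(n_patients=300, seed=9)).resources)
config = PipelineConfig(task=Task.MORTALITY, seed=4)
prepared = prepare(parsed, config)
samples = materialize(prepared, config)
fit = fit_and_score(samples, LabelKind.BINARY, backend=BackendSpec(seed=4))

probs = fit.model.predict_proba([s.text for s in samples])
now = dt.datetime(2024, 1, 15, 9, 30, tzinfo=dt.timezone.utc)
records = build_assessments(probs, prepared.windows, Task.MORTALITY,
                            model_version="fhirpipe-0.1.0", now=now)
print(f"emitted {len(records)} RiskAssessment records; first resource:\n")
resource = write_riskassessment(records[0])
print(json.dumps(resource, indent=2, sort_keys=True))

assert parse_riskassessment(resource) == records[0]
print("\nround trip OK: re-parsing the JSON recovers the record exactly")
# prediction[0].probabilityDecimal is the in-hospital mortality risk score
# in [0, 1]; subject/encounter references tie it back to the patient chart.
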