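# Methods

This note documents the models, conventions and numerical choices behind
fhirpipe: what each stage computes, which parameters matter, what the
synthetic data generator does and does not emulate, and the design
decisions taken where more than one convention was defensible.

## Timestamps and time conventions

All timestamps are timezone-aware UTC; offset-bearing FHIR values are
converted, naive values assumed UTC, and date-only values interpreted as
00:00:00 UTC. This makes window cutoffs reproducible across machines and
locales. Each resource type has a fixed timestamp source with a
deterministic fallback chain (e.g. Condition: recordedDate, else
onsetDateTime; Observation: effectiveDateTime, else issued; Procedure:
performedDateTime, else performedPeriod.start) chosen as the earliest
clinically meaningful instant. Events with no resolvable timestamp cannot
be placed relative to a cutoff and are skipped with a warning rather than
guessed.

Derived time quantities use explicit conventions: stay length in days is
the ceiling of (discharge − admission)/24 h, so "at least two days" means
≥ 2 by that measure; age is computed at encounter start and floored to
whole years; expanding windows are anchored to UTC calendar dates (cutoff
23:59:59 of each date, clamped to discharge), not admission-anchored 24 h
blocks, so a stay spanning 12 calendar dates yields exactly 12 windows.

## Encounter merging

Hospital-internal transfers commonly appear as back-to-back Encounter
resources. Overlapping encounters of one patient are merged into a single
stay (min start, max end, death flags OR-ed) before any cohort rule,
window or label is computed; otherwise a transfer would masquerade as a
30-day readmission.

## Task definitions and leakage control

| task        | label                                                        | sliding cutoff      |
|-------------|--------------------------------------------------------------|---------------------|
| readmission | another merged stay starts in (discharge, discharge + 30 d]  | discharge           |
| mortality   | death timestamp in [admission, discharge] or death disposition | discharge         |
| imaging     | DICOM modalities of studies started in [admission, +24 h)    | admission           |
| icd         | 3-char ICD categories recorded in (admission + 24 h, discharge] | admission + 24 h |

The cutoff for each task is chosen so the label-defining interval lies
strictly beyond it; a window's features are exactly the patient's events
with timestamp ≤ cutoff (full prior history by default, optionally
bounded by `history_days`). Expanding windows are only offered for the
outcome-at-discharge tasks (readmission, mortality): for imaging/icd the
daily cutoffs would overlap the label interval, so those combinations are
rejected rather than silently leaking.

The readmission interval is half-open at discharge and closed at day 30 —
a stay starting at the discharge instant is a transfer artifact (and is
merged away anyway), while one starting exactly 30 days later counts.
Multilabel label spaces (imaging modalities, ICD categories) are built
from the training split only, capped to the 100 most frequent codes
(ties alphabetical), and then applied to every split, mirroring
deployment-time alignment; the cap keeps macro metrics meaningful at the
population sizes this package targets.

For expanding windows the label is computed once per encounter and
attached to each daily window; the daily features remain cutoff-limited.

## Serialization

Each window becomes one document: a demographics header
(`Patient | age <band> | sex <sex> | insurance <insurance>`), then one
line per event — `<ISO date> | <resource type> | <code display or code> |
<value or text excerpt>` — filtered by per-resource-type inclusion flags,
sorted by configurable keys (timestamp by default), and deduplicated on
(resource type, primary code, calendar date) keeping the earliest
occurrence. Free-text payloads are clipped to 500 characters per event
before budget accounting. Over the document budget, the *oldest* lines
are dropped first: the most recent clinical state is the most predictive
for these tasks. The default budget is 2048 characters, sized to mirror
the ~512-token input of the BERT-family encoders this text format is
designed to feed (≈4 characters/token); the character budget keeps the
core tokenizer-independent, and a transformer adapter may re-truncate.

Splits hash (seed, patient_id) through SHA-256 into train/val/test, so
all samples of a patient share a split and the patient sets are disjoint
by construction; empirical fractions converge to the targets within ±2%
by about a thousand patients.

## Modeling backend

The required backend is deliberately desk-scale: hashed bag-of-words
features (2^18 dimensions, unsigned counts) with L2-regularized logistic
regression (liblinear solver, deterministic given the seed; C=1.0,
class weights balanced for binary tasks), one-vs-rest for multilabel. A
label never (or always) positive in training gets a smoothed-prevalence
constant scorer instead of a degenerate fit. Probabilities are exactly
the logistic transform of the linear scores. Transformer encoders fit the
same backend contract (a checkpoint-name string in the config) but are
not bundled.

Metrics: binary accuracy/precision/recall/F1 at a 0.5 threshold (zero
denominators score 0) with threshold-free ROC AUC; multilabel exact-match
accuracy, macro precision/recall/F1 averaged over the *full* label space
(classes that never occur contribute 0), and top-k variants. "Top-k
accuracy" counts a sample as a hit iff *every* true label is among the k
highest-scoring labels (ties broken toward the lower label index; an
"any-label" variant is available) — a declared convention, since several
are defensible; top-k macro metrics are computed from the binarized
in-top-k predictions. The validation loss minimized by sweeps is mean
binary cross-entropy (per label for multilabel), clipped at 1e-12.

## Sweeps and importance

The sweep driver is a seeded local random search over a user-declared
space (choice lists and log/linear ranges), replacing a hosted Bayesian
service so that no network dependency exists; the search-space semantics
(resource-inclusion flags plus training hyperparameters, objective =
validation loss, run budget, optional per-run subsample cap of 100 000
training samples) are unchanged. Best run = argmin validation loss, ties
broken by higher validation F1 then lower run id.

Parameter importance is the permutation importance of a random-forest
surrogate (200 trees, 10 repeats, seeded) fit on configurations →
target metric, clipped at zero and normalized to sum 1 (uniform if the
surrogate finds nothing); correlation is the Pearson correlation of each
parameter (booleans as 0/1) with the target across runs, 0 with a flag
for constant parameters. With a budget of 10 the surrogate sees only 10
points, so importance attribution is reliable only when per-run
validation loss is dominated by the ablation effect rather than by
evaluation noise; the bundled sweep study therefore uses a 1500-patient
population (~3700 windows, ~550 validation windows), at which the
signal-bearing flag is recovered as top-ranked essentially always.

## Synthetic population generator

The generator emulates the *structure* of inpatient FHIR data: patients
with demographics and Coverage-derived insurance (75/7/18%
statutory/private/unknown), 2–8 completed stays of 1–9 days, and per-day
Observations (LOINC-coded quantities), Medications (ATC), Procedures
(OPS-style), DiagnosticReports with templated free-text conclusions,
ServiceRequests, ImagingStudy series with DICOM modalities, one
EpisodeOfCare per patient, and a tagged main diagnosis per stay drawn
from an embedded ~50-code ICD-10-GM-style vocabulary.

Planted effects, all configurable:

* **Readmission.** Each stay independently records the risk condition
  (default I50.9, probability 0.5) and draws a 30-day readmission coin at
  p1 = 0.9 if it did, p0 = 0.1 otherwise. Crucially, the *number* of
  stays is drawn before any coin, every patient has at least two
  completed stays, inter-stay gaps realize the coins (1–29 d vs 40–200 d),
  and a positive coin on the final completed stay is realized as an
  ongoing admission (no discharge yet) that the labeler can see but the
  sampler never emits. This construction makes each stay's label an
  independent coin given its own risk flag: chain length, stay position
  and cohort inclusion carry no label information, so a pipeline run on a
  null configuration (p1 = p0) measures chance-level AUC, and any
  systematic excess would indicate leakage in the pipeline itself.
  Deceased patients draw no readmission.
* **Mortality.** Death probability 0.01 + 0.004·max(age − 60, 0),
  capped at 0.6; deaths occur in the final stay and set both the
  patient's deceasedDateTime and an "exp" discharge disposition.
* **Imaging.** Per modality (CT, MR), a ServiceRequest marker authored
  at the admission instant (probability 0.35) raises the probability of a
  matching study in the first 24 h to 0.9 (vs 0.05 without); US/CR
  studies are pure noise, and occasional post-24 h studies exercise the
  label window boundary.
* **ICD.** Conditions after the first day (Poisson mean 1.5 per stay)
  are foreshadowed, with probability 0.9, by an admission-day
  DiagnosticReport conclusion naming the code category.

The ground-truth table (one row per completed stay) is derived from the
generated timeline by construction, independently of the labeling code,
so pipeline-vs-truth comparison is a genuine two-route check; for
readmission and mortality the match must be exact.

What the generator does **not** emulate: clinical plausibility of code
co-occurrence, German free-text, measurement noise correlated with
outcomes, censoring, coding-practice drift, or cross-institution
variation. Passing tests therefore establish the pipeline's mechanical
correctness (parsing, windowing, leakage control, label rules, metric
arithmetic, reproducibility) and its ability to recover planted signals
through the full text path — not expected performance on real EHR data.

## Problem sizes and reproducibility

The bundled studies run on one CPU in minutes: label-oracle and
signal-recovery checks use 2000-patient populations (~4800 stays,
~110 000 resources), the leakage property uses 100 populations of 10
patients across all four tasks, and the sweep study uses 1500 patients
with 10 sweeps of budget 10. Every source of randomness flows from a
single seed through a stage-name-keyed SHA-256 derivation (always below
2^31), and identical configuration plus seed reproduces sample, label and
metric files byte for byte.

## Known limitations

* `push_resources` is a thin synchronous client (stdlib urllib) intended
  for small batches and tests, not a bulk loader.
* Insurance mapping covers common German coverage codes by default;
  other systems need a custom code table (anything unmapped is
  "unknown").
* Mortality cohort: "patients with a single hospital admission" is read
  as ≥1 admission; an `exactly_one` switch exposes the stricter reading.
* RiskAssessment output populates a minimal conformant field set
  (status, subject, encounter, method, note, occurrence, one prediction
  with probabilityDecimal); profile-specific extensions are out of scope.
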