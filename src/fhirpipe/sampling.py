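"""Sliding- and expanding-window sample generation.

The two strategies structure longitudinal inpatient data without temporal
leakage:

* sliding — one sample per (merged) encounter, cutoff at discharge (or a
  task-supplied cutoff such as admission + 24 h); the patient's full prior
  history is visible by default, optionally bounded by ``history_days``;
* expanding — one cumulative sample per UTC calendar date of a single
  stay, cutoff at 23:59:59 UTC of that date (clamped to discharge), so
  day k's event set is nested in day k+1's.

Both guarantee by construction that no event past the cutoff is visible.
"""

from __future__ import annotations

import bisect
import datetime as dt
import logging
from typing import Optional, Sequence

from ._time import DAY, end_of_utc_day
from .types import ClinicalEvent, EncounterRecord, SampleWindow, Strategy

logger = logging.getLogger(__name__)


class _PatientTimeline:
    """Events of one patient sorted by (timestamp, event_id), with
    bisection by cutoff so window extraction is O(log n) per window."""

    def __init__(self, events: list[ClinicalEvent]):
        events = sorted(events, key=lambda e: (e.timestamp, e.event_id))
        self.timestamps = [e.timestamp for e in events]
        self.event_ids = [e.event_id for e in events]

    def visible(self, cutoff: dt.datetime,
                history_start: Optional[dt.datetime]) -> tuple[str, ...]:
        hi = bisect.bisect_right(self.timestamps, cutoff)
        lo = 0
        if history_start is not None:
            lo = bisect.bisect_left(self.timestamps, history_start)
        return tuple(self.event_ids[lo:hi])


def _group_by_patient(events: Sequence[ClinicalEvent]) -> dict[str, _PatientTimeline]:
    grouped: dict[str, list[ClinicalEvent]] = {}
    for ev in events:
        grouped.setdefault(ev.patient_id, []).append(ev)
    return {pid: _PatientTimeline(evs) for pid, evs in grouped.items()}


_EMPTY_TIMELINE = _PatientTimeline([])


def sliding_windows(
    encounters: Sequence[EncounterRecord],
    events: Sequence[ClinicalEvent],
    cutoff_override: Optional[dict[str, dt.datetime]] = None,
    history_days: Optional[int] = None,
) -> list[SampleWindow]:
    """One window per completed encounter; each stay is an independent sample.

    ``cutoff_override`` maps encounter_id to a task-specific cutoff (eg
    admission + 24 h for the imaging task). Encounters with no end and no
    override are skipped with a warning.
    """
    timelines = _group_by_patient(events)
    windows: list[SampleWindow] = []
    for enc in sorted(encounters, key=lambda e: (e.patient_id, e.start, e.encounter_id)):
        cutoff = (cutoff_override or {}).get(enc.encounter_id, enc.end)
        if cutoff is None:
            logger.warning("encounter %s has no end and no cutoff override; skipped",
                           enc.encounter_id)
            continue
        history_start = None
        if history_days is not None:
            history_start = cutoff - dt.timedelta(days=history_days)
        timeline = timelines.get(enc.patient_id, _EMPTY_TIMELINE)
        windows.append(SampleWindow(
            patient_id=enc.patient_id,
            encounter_id=enc.encounter_id,
            strategy=Strategy.SLIDING,
            cutoff=cutoff,
            history_start=history_start,
            event_ids=timeline.visible(cutoff, history_start),
        ))
    return windows


def expanding_windows(
    encounter: EncounterRecord,
    events: Sequence[ClinicalEvent],
) -> list[SampleWindow]:
    """One cumulative window per UTC calendar date intersecting the stay.

    Window for date d has cutoff min(discharge, 23:59:59 UTC of d) and a
    1-based day_index. An ongoing encounter (no end) expands up to the last
    observed event of the patient.
    """
    end = encounter.end
    if end is None:
        patient_events = [e for e in events if e.patient_id == encounter.patient_id]
        if not patient_events:
            end = encounter.start
        else:
            end = max(e.timestamp for e in patient_events)
            end = max(end, encounter.start)
    if end < encounter.start:
        raise ValueError(
            f"encounter {encounter.encounter_id}: end {end} before start {encounter.start}"
        )
    timeline = _PatientTimeline(
        [e for e in events if e.patient_id == encounter.patient_id])
    windows: list[SampleWindow] = []
    day = encounter.start.date()
    index = 1
    while day <= end.date():
        cutoff = min(end, end_of_utc_day(day))
        windows.append(SampleWindow(
            patient_id=encounter.patient_id,
            encounter_id=encounter.encounter_id,
            strategy=Strategy.EXPANDING,
            cutoff=cutoff,
            history_start=None,
            event_ids=timeline.visible(cutoff, None),
            day_index=index,
        ))
        day = day + DAY
        index += 1
    return windows
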