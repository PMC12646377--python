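"""Sliding vs expanding windows on one patient's timeline.

A 12-day admission produces 12 expanding windows (one cumulative sample
per calendar date); two separate admissions produce 2 sliding windows
(one independent sample per stay). No window ever sees an event after its
cutoff.
"""

import datetime as dt

from fhirpipe import expanding_windows, sliding_windows
from fhirpipe.types import ClinicalEvent, Coding, EncounterRecord

UTC = dt.timezone.utc
start = dt.datetime(2021, 3, 1, 15, tzinfo=UTC)
stay = EncounterRecord("stay-1", "p1", start, start + dt.timedelta(days=11))
events = [
    ClinicalEvent(f"obs-{i}", "p1", "Observation",
                  start + dt.timedelta(days=i, hours=2),
                  codes=(Coding("loinc", "718-7", "Hemoglobin"),))
    for i in range(12)
]

daily = expanding_windows(stay, events)
print(f"expanding: {len(daily)} windows for a stay spanning 12 calendar dates")
for window in daily[:3]:
    print(f"  day {window.day_index}: cutoff {window.cutoff:%Y-%m-%d %H:%M}, "
          f"{len(window.event_ids)} visible events")
print("  ... each day's event set is nested in the next day's\n")

second = EncounterRecord("stay-2", "p1", start + dt.timedelta(days=90),
                         start + dt.timedelta(days=101))
per_stay = sliding_windows([stay, second], events)
print(f"sliding: {len(per_stay)} windows for 2 completed admissions")
print(f"  stay-2 window sees {len(per_stay[1].event_ids)} events "
      "(full prior history included by default)")
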