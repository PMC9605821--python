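"""Detect hematologic dysfunction episodes for one hand-built patient.

A 48-hour stay with a platelet drop below 80,000/mm3 followed by an
overlapping INR elevation above 2: the two alarms concatenate into one
episode attributed to both causes.
"""

from datetime import datetime, timedelta

from hemod import (
    Analyte,
    LabObservation,
    PatientRecord,
    RuleConfig,
    detect_hematologic_od,
    merge_alarm_events,
    raw_alarm_events,
)

t0 = datetime(2024, 3, 1, 8, 0)
hh = lambda x: t0 + timedelta(hours=x)

patient = PatientRecord(
    patient_id="DEMO-1",
    age_years=4.0,
    admission=t0,
    discharge=hh(48),
    observations=(
        LabObservation("DEMO-1", Analyte.PLT, 210_000, hh(1)),
        LabObservation("DEMO-1", Analyte.PLT, 62_000, hh(10)),   # < 80,000 -> alarm
        LabObservation("DEMO-1", Analyte.PLT, 135_000, hh(22)),  # recovered
        LabObservation("DEMO-1", Analyte.INR, 1.1, hh(2)),
        LabObservation("DEMO-1", Analyte.INR, 2.6, hh(18)),      # > 2 -> alarm
        LabObservation("DEMO-1", Analyte.INR, 1.4, hh(30)),
    ),
)

config = RuleConfig()
print("merged alarm events:")
for ev in merge_alarm_events(raw_alarm_events(patient, config)):
    print(f"  {ev.analyte.value:3} {ev.category.value:8} [{ev.start:%H:%M} - {ev.end:%H:%M}] ({ev.criterion.value})")

print("dysfunction episodes:")
for ep in detect_hematologic_od(patient, config):
    hours = (ep.end - ep.start).total_seconds() / 3600
    print(f"  [{ep.start:%Y-%m-%d %H:%M} - {ep.end:%H:%M}] cause={ep.cause.value} ({hours:.0f} h)")

# The platelet alarm [10:00+10h, 10:00+22h] and the INR alarm starting at
# +18h overlap, so a single episode spanning their union is reported with
# cause BOTH: the stay contains one hematologic dysfunction episode
# driven first by thrombocytopenia, then by coagulopathy.
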