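"""Shared fixtures and the independent brute-force detection oracle."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from hemod.types import (
    Analyte,
    LabObservation,
    ODCause,
    PatientRecord,
    RuleConfig,
)

T0 = datetime(2024, 3, 1, 0, 0)


def h(hours: float) -> datetime:
    """Instant ``hours`` after the canonical admission time."""
    return T0 + timedelta(hours=hours)


def make_patient(
    plt=(),
    inr=(),
    stay_hours: float = 48.0,
    diagnoses=(),
    procedures=(),
    patient_id: str = "P1",
    age: float = 5.0,
) -> PatientRecord:
    """Build a patient from (offset_hours, value) pairs per analyte."""
    obs = [
        LabObservation(patient_id, Analyte.PLT, v, h(t)) for t, v in plt
    ] + [
        LabObservation(patient_id, Analyte.INR, v, h(t)) for t, v in inr
    ]
    obs.sort(key=lambda o: o.timestamp)
    return PatientRecord(
        patient_id, age, T0, h(stay_hours), tuple(obs), tuple(diagnoses), tuple(procedures)
    )


def brute_force_episodes(patient: PatientRecord, config: RuleConfig):
    """Independent oracle for confounder-free patients.

    Classifies every observation on its own against the plain absolute
    thresholds and reconstructs maximal abnormal runs: an abnormal run
    spans from its first observation to the next observation with a
    different classification (discharge if none). Platelet-low and
    INR-high runs whose intervals overlap or touch combine into one
    episode attributed to both causes. No chronic, exclusion, or ECMO
    handling — callers must only use it on patients without those
    features.
    """
    runs = {}
    for analyte, abnormal in ((Analyte.PLT, "low"), (Analyte.INR, "high")):
        obs = sorted(
            (o for o in patient.observations if o.analyte is analyte),
            key=lambda o: o.timestamp,
        )

        def classify(o):
            if o.analyte is Analyte.PLT:
                if o.value < config.plt_min:
                    return "low"
                if o.value > config.plt_max_plausible:
                    return "high"
            else:
                if o.value > config.inr_max:
                    return "high"
                if o.value < config.inr_min_plausible:
                    return "low"
            return "normal"

        labels = [classify(o) for o in obs]
        intervals = []
        i = 0
        while i < len(obs):
            if labels[i] != abnormal:
                i += 1
                continue
            j = i
            while j < len(obs) and labels[j] == abnormal:
                j += 1
            end = obs[j].timestamp if j < len(obs) else patient.discharge
            if obs[i].timestamp < end:
                intervals.append((obs[i].timestamp, end))
            i = j
        runs[analyte] = intervals

    tagged = sorted(
        [(s, e, "plt") for s, e in runs[Analyte.PLT]]
        + [(s, e, "inr") for s, e in runs[Analyte.INR]]
    )
    episodes = []
    for s, e, src in tagged:
        if episodes and s <= episodes[-1][1]:
            episodes[-1][1] = max(episodes[-1][1], e)
            episodes[-1][2].add(src)
        else:
            episodes.append([s, e, {src}])
    return [
        (s, e, ODCause.BOTH if len(srcs) > 1 else (ODCause.PLATELETS if "plt" in srcs else ODCause.INR))
        for s, e, srcs in episodes
    ]


@pytest.fixture
def default_config() -> RuleConfig:
    return RuleConfig()
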