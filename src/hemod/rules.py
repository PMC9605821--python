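"""Rule engine: specify -> select -> evaluate inference chain.

Implements the (site-modified) IPSCC hematologic organ-dysfunction
criteria on sparse laboratory time series:

* platelet count < ``plt_min`` (default 80,000/mm**3), or
* in patients with a documented chronic hematology/oncology diagnosis,
  a decline of at least ``decline_fraction`` (default 50%) versus the
  first platelet value after admission (the baseline), or
* INR > ``inr_max`` (default 2), unless the patient carries a diagnosis
  known to raise INR independently of sepsis.

A point measurement becomes an interval by persistence: an abnormal
value holds from its specimen timestamp until the next same-analyte
observation with a different alarm category, else until discharge.
Platelet alarms inside extended ECMO windows (2 h pre / 12 h post by
default) are suppressed to avoid circuit-related false positives.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Optional, Sequence

from .intervals import merge_touching, subtract
from .types import (
    AlarmCategory,
    AlarmCriterion,
    AlarmEvent,
    Analyte,
    LabObservation,
    NormRange,
    ODCause,
    ODEpisode,
    PatientRecord,
    RuleConfig,
)


def specify_norm(analyte: Analyte, config: RuleConfig) -> NormRange:
    """Assign the normal range for ``analyte`` from the rule configuration.

    The diagnostic criteria fix one boundary per analyte (platelet
    minimum, INR maximum); the other boundary is a plausibility bound.
    """
    if analyte is Analyte.PLT:
        return NormRange(Analyte.PLT, config.plt_min, config.plt_max_plausible)
    if analyte is Analyte.INR:
        return NormRange(Analyte.INR, config.inr_min_plausible, config.inr_max)
    raise ValueError(f"unknown analyte: {analyte!r}; expected PLT or INR")


def evaluate_observation(obs: LabObservation, norm: NormRange) -> AlarmCategory:
    """Classify one observation against its norm range.

    Boundary values are NORMAL: the criteria are strict ("<80,000", ">2").
    """
    if obs.analyte is not norm.analyte:
        raise ValueError(
            f"analyte mismatch: observation is {obs.analyte.value}, "
            f"norm range is for {norm.analyte.value}"
        )
    if obs.value < norm.minimum:
        return AlarmCategory.TOO_LOW
    if obs.value > norm.maximum:
        return AlarmCategory.TOO_HIGH
    return AlarmCategory.NORMAL


def baseline_platelet(patient: PatientRecord) -> Optional[LabObservation]:
    """First platelet value at or after admission (the decline comparator).

    Using the first value instead of a rolling maximum avoids
    adulteration by platelet transfusions or surgical bleeding.
    """
    plt = [o for o in patient.observations if o.analyte is Analyte.PLT]
    if not plt:
        return None
    return min(plt, key=lambda o: o.timestamp)


def _code_matches(code: str, targets: Sequence[str], prefix: bool) -> bool:
    if prefix:
        return any(code.startswith(t) for t in targets)
    return code in targets


def applies_chronic_rule(patient: PatientRecord, config: RuleConfig) -> bool:
    """Whether the relative platelet-decline criterion applies to this patient."""
    return any(
        _code_matches(d.icd10gm_code, config.chronic_hemonc_codes, config.code_prefix_match)
        for d in patient.diagnoses
    )


def inr_excluded(patient: PatientRecord, config: RuleConfig) -> bool:
    """Whether elevated INR is discounted for this patient.

    True when any diagnosis matches the exclusion list (e.g., hereditary
    coagulation-factor deficiencies); no INR alarm then contributes to
    dysfunction episodes.
    """
    return any(
        _code_matches(d.icd10gm_code, config.inr_exclusion_codes, config.code_prefix_match)
        for d in patient.diagnoses
    )


def extended_ecmo_windows(
    patient: PatientRecord, config: RuleConfig
) -> list[tuple[datetime, datetime]]:
    """ECMO episodes widened by the pre/post margins, merged when overlapping."""
    pre = timedelta(hours=config.ecmo_pre_hours)
    post = timedelta(hours=config.ecmo_post_hours)
    windows = [
        (p.start - pre, p.end + post)
        for p in patient.procedures
        if p.procedure == "ECMO"
    ]
    return merge_touching(windows)


def _effective_category(
    obs: LabObservation,
    norm: NormRange,
    chronic: bool,
    baseline: Optional[LabObservation],
    config: RuleConfig,
) -> tuple[AlarmCategory, AlarmCriterion]:
    """Alarm category of one observation, with criterion attribution.

    The relative-decline rule fires for chronic patients when the value
    is at or below (1 - decline_fraction) x baseline; the baseline
    observation itself never triggers it. When both the absolute and the
    relative criterion hold, the absolute one is attributed.
    """
    cat = evaluate_observation(obs, norm)
    if cat is not AlarmCategory.NORMAL:
        return cat, AlarmCriterion.ABSOLUTE
    if (
        chronic
        and obs.analyte is Analyte.PLT
        and baseline is not None
        and obs is not baseline
        and obs.value <= (1.0 - config.decline_fraction) * baseline.value
    ):
        return AlarmCategory.TOO_LOW, AlarmCriterion.RELATIVE_DECLINE
    return AlarmCategory.NORMAL, AlarmCriterion.ABSOLUTE


def raw_alarm_events(patient: PatientRecord, config: RuleConfig) -> list[AlarmEvent]:
    """Per-observation alarm events before merging.

    Each abnormal observation opens an event at its timestamp; the event
    closes at the next same-analyte observation whose category differs,
    else at discharge.
    """
    events: list[AlarmEvent] = []
    chronic = applies_chronic_rule(patient, config)
    baseline = baseline_platelet(patient)
    for analyte in Analyte:
        norm = specify_norm(analyte, config)
        obs = sorted(
            (o for o in patient.observations if o.analyte is analyte),
            key=lambda o: o.timestamp,
        )
        classified = [
            _effective_category(o, norm, chronic, baseline, config) for o in obs
        ]
        for i, (o, (cat, crit)) in enumerate(zip(obs, classified)):
            if cat is AlarmCategory.NORMAL:
                continue
            end = patient.discharge
            for j in range(i + 1, len(obs)):
                if classified[j][0] is not cat:
                    end = obs[j].timestamp
                    break
            if o.timestamp < end:
                events.append(
                    AlarmEvent(patient.patient_id, analyte, cat, crit, o.timestamp, end)
                )
    return events


def merge_alarm_events(events: Sequence[AlarmEvent]) -> list[AlarmEvent]:
    """Merge simultaneous events of the same analyte and alarm category.

    The united event spans from the start of the first to the end of the
    last overlapping event; touching events merge too. When merged events
    mix criteria, ABSOLUTE is attributed.
    """
    groups: dict[tuple[str, Analyte, AlarmCategory], list[AlarmEvent]] = {}
    for ev in events:
        groups.setdefault((ev.patient_id, ev.analyte, ev.category), []).append(ev)
    merged: list[AlarmEvent] = []
    for (pid, analyte, cat), group in groups.items():
        group.sort(key=lambda ev: (ev.start, ev.end))
        runs: list[list[AlarmEvent]] = []
        for ev in group:
            if runs and ev.start <= runs[-1][-1].end:
                runs[-1].append(ev)
            else:
                runs.append([ev])
        for run in runs:
            crit = (
                AlarmCriterion.ABSOLUTE
                if any(ev.criterion is AlarmCriterion.ABSOLUTE for ev in run)
                else AlarmCriterion.RELATIVE_DECLINE
            )
            merged.append(
                AlarmEvent(
                    pid,
                    analyte,
                    cat,
                    crit,
                    run[0].start,
                    max(ev.end for ev in run),
                )
            )
    merged.sort(key=lambda ev: (ev.start, ev.end, ev.analyte.value, ev.category.value))
    return merged


def ecmo_suppressed_intervals(
    patient: PatientRecord, config: RuleConfig
) -> list[tuple[datetime, datetime]]:
    """Portions of platelet alarms removed by ECMO suppression.

    These never become dysfunction episodes but can be surfaced as
    non-diagnostic warnings (e.g., in reports).
    """
    from .intervals import intersect

    merged = merge_alarm_events(raw_alarm_events(patient, config))
    plt_low = [
        (ev.start, ev.end)
        for ev in merged
        if ev.analyte is Analyte.PLT and ev.category is AlarmCategory.TOO_LOW
    ]
    return intersect(plt_low, extended_ecmo_windows(patient, config))


def detect_hematologic_od(patient: PatientRecord, config: RuleConfig) -> list[ODEpisode]:
    """Hematologic organ-dysfunction episodes for one stay.

    Platelet TOO_LOW alarms (minus extended ECMO windows) and INR
    TOO_HIGH alarms (unless excluded by diagnosis) become episodes;
    overlapping or touching platelet and INR episodes concatenate into a
    single episode attributed to both causes. Platelet TOO_HIGH and INR
    TOO_LOW alarms never produce dysfunction.
    """
    merged = merge_alarm_events(raw_alarm_events(patient, config))
    plt_low = [
        (ev.start, ev.end)
        for ev in merged
        if ev.analyte is Analyte.PLT and ev.category is AlarmCategory.TOO_LOW
    ]
    plt_low = subtract(plt_low, extended_ecmo_windows(patient, config))
    if inr_excluded(patient, config):
        inr_high: list[tuple[datetime, datetime]] = []
    else:
        inr_high = [
            (ev.start, ev.end)
            for ev in merged
            if ev.analyte is Analyte.INR and ev.category is AlarmCategory.TOO_HIGH
        ]

    tagged = [(s, e, ODCause.PLATELETS) for s, e in plt_low] + [
        (s, e, ODCause.INR) for s, e in inr_high
    ]
    tagged.sort(key=lambda t: (t[0], t[1]))
    episodes: list[ODEpisode] = []
    cur: Optional[tuple[datetime, datetime, set[ODCause]]] = None
    for s, e, cause in tagged:
        if cur is not None and s <= cur[1]:
            cur = (cur[0], max(cur[1], e), cur[2] | {cause})
        else:
            if cur is not None:
                episodes.append(_finish_episode(patient.patient_id, cur))
            cur = (s, e, {cause})
    if cur is not None:
        episodes.append(_finish_episode(patient.patient_id, cur))
    return episodes


def _finish_episode(pid: str, cur: tuple[datetime, datetime, set[ODCause]]) -> ODEpisode:
    causes = cur[2]
    cause = ODCause.BOTH if len(causes) > 1 else next(iter(causes))
    return ODEpisode(pid, cur[0], cur[1], cause)


__all__ = [
    "specify_norm",
    "evaluate_observation",
    "baseline_platelet",
    "applies_chronic_rule",
    "inr_excluded",
    "extended_ecmo_windows",
    "raw_alarm_events",
    "merge_alarm_events",
    "ecmo_suppressed_intervals",
    "detect_hematologic_od",
]
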