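"""Synthetic PICU cohorts with injected hematologic dysfunction episodes.

Each patient gets latent platelet and INR trajectories: a baseline
plateau, and during injected episodes a trapezoidal excursion (linear
descent over the first quarter of the episode, a nadir/peak plateau over
the middle half, linear recovery over the last quarter). Observations
are irregular samples of the latent curves with multiplicative
lognormal noise. Ground-truth dysfunction episodes are the intervals
where the *noise-free latent curve* violates the rule thresholds
(absolute platelet minimum, chronic relative decline versus the latent
baseline, INR maximum with the exclusion-diagnosis gate), so detection
quality under noise and sparse sampling is measurable rather than
tautological. ECMO suppression is deliberately NOT applied to the
truth: extended ECMO windows act as a false-negative source for the
detector, as they do clinically.

All randomness flows from one seed through per-patient substreams
(numpy SeedSequence spawning), so adding patients never perturbs
existing ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace as dc_replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .intervals import merge_touching
from .types import (
    Analyte,
    DiagnosisRecord,
    LabObservation,
    PatientRecord,
    ProcedureEpisode,
    ReferenceEpisode,
    RuleConfig,
)

logger = logging.getLogger(__name__)

_BASE_ADMISSION = datetime(2023, 1, 2, 8, 0)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the study population: 0-18-year patients, stays of
    a few days (>=12 h), sparse irregular lab sampling, roughly one in
    five patients with at least one dysfunction episode, and small
    prevalences of chronic hematology/oncology diagnoses, INR-raising
    primary diseases, and ECMO runs.
    """

    n_patients: int = 168
    seed: int = 0
    stay_median_days: float = 3.0
    stay_sigma: float = 0.5  # lognormal shape; floor 0.5 days
    plt_sampling_hours: tuple[float, float] = (6.0, 24.0)
    inr_sampling_hours: tuple[float, float] = (12.0, 48.0)
    baseline_plt_range: tuple[float, float] = (150_000.0, 450_000.0)
    inr_baseline_range: tuple[float, float] = (0.9, 1.3)
    episode_prevalence: float = 0.21
    episodes_per_affected: tuple[int, int] = (1, 3)
    episode_duration_hours: tuple[float, float] = (12.0, 96.0)
    plt_nadir_fraction: float = 0.2
    inr_peak_range: tuple[float, float] = (2.2, 4.0)
    chronic_prevalence: float = 0.1
    inr_exclusion_prevalence: float = 0.05
    ecmo_prevalence: float = 0.05
    noise_cv: float = 0.05
    error_spike_rate: float = 0.0
    # episodes begin at least this long after admission (a baseline
    # sample window) and are separated by at least this gap, so distinct
    # injected episodes stay distinct under the 24 h evaluation merge
    episode_earliest_start_hours: float = 6.0
    min_episode_gap_hours: float = 36.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "episode_prevalence",
            "chronic_prevalence",
            "inr_exclusion_prevalence",
            "ecmo_prevalence",
            "error_spike_rate",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "plt_sampling_hours",
            "inr_sampling_hours",
            "baseline_plt_range",
            "inr_baseline_range",
            "episode_duration_hours",
            "inr_peak_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} range must be ordered, got ({lo}, {hi})")

    @classmethod
    def dense_noise_free(cls, n_patients: int, seed: int, **overrides) -> "SimConfig":
        """Confounder-free scenario: hourly sampling, no noise, no ECMO,
        no chronic or INR-exclusion diagnoses. Under it the detector
        recovers the injected truth exactly (up to the evaluation's
        snapping tolerance)."""
        kwargs = dict(
            n_patients=n_patients,
            seed=seed,
            plt_sampling_hours=(0.5, 1.0),
            inr_sampling_hours=(0.5, 1.0),
            noise_cv=0.0,
            chronic_prevalence=0.0,
            inr_exclusion_prevalence=0.0,
            ecmo_prevalence=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class _Episode:
    start_h: float  # offset from admission, hours
    duration_h: float
    kind: str  # "plt" | "inr" | "both"
    inr_peak: float

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h


@dataclass
class SyntheticCohort:
    """A generated cohort plus its injected ground truth and provenance."""

    patients: list[PatientRecord]
    truth: list[ReferenceEpisode]
    provenance: dict

    def truth_for(self, patient_id: str) -> list[ReferenceEpisode]:
        return [t for t in self.truth if t.patient_id == patient_id]


def _trapezoid(t_h: float, ep: _Episode, base: float, extreme: float) -> Optional[float]:
    """Latent value inside an episode: descend 1/4, plateau 1/2, recover 1/4."""
    if not ep.start_h <= t_h <= ep.end_h:
        return None
    q = ep.duration_h / 4.0
    if t_h < ep.start_h + q:
        frac = (t_h - ep.start_h) / q
    elif t_h > ep.end_h - q:
        frac = (ep.end_h - t_h) / q
    else:
        frac = 1.0
    return base + (extreme - base) * frac


def _crossing(
    ep: _Episode, base: float, extreme: float, threshold: float, below: bool
) -> Optional[tuple[float, float]]:
    """Interval (hours) where the trapezoid is past ``threshold``.

    ``below=True`` asks where the curve is under the threshold (platelet
    rules), ``below=False`` where it is above (INR rule). Returns None
    when the plateau never reaches the threshold.
    """
    if below and not extreme < threshold:
        return None
    if not below and not extreme > threshold:
        return None
    frac = (base - threshold) / (base - extreme)  # same sign either way
    if frac <= 0:  # baseline already past threshold; treat whole episode
        return (ep.start_h, ep.end_h)
    q = ep.duration_h / 4.0
    return (ep.start_h + q * frac, ep.end_h - q * frac)


def _round_minute(base: datetime, offset_h: float, up: bool = False) -> datetime:
    minutes = offset_h * 60.0
    m = math.ceil(minutes) if up else math.floor(minutes)
    return base + timedelta(minutes=m)


def _sample_times(rng: np.random.Generator, stay_h: float, interval: tuple[float, float]) -> list[float]:
    """Irregular sampling offsets: admission labs within 2 h, then draws
    from the configured inter-sample interval."""
    t = float(rng.uniform(0.25, min(2.0, stay_h / 2.0)))
    out = [t]
    while True:
        t += float(rng.uniform(*interval))
        if t > stay_h:
            break
        out.append(t)
    return out


def _generate_patient(
    index: int,
    ss: np.random.SeedSequence,
    cfg: SimConfig,
    rules: RuleConfig,
) -> tuple[PatientRecord, list[ReferenceEpisode], int, int]:
    rng = np.random.default_rng(ss)
    pid = f"P{index:05d}"
    age = float(rng.uniform(0.0, 18.0))
    stay_d = max(0.5, float(rng.lognormal(math.log(cfg.stay_median_days), cfg.stay_sigma)))
    stay_h = round(stay_d * 24.0 * 60.0) / 60.0
    admission = _BASE_ADMISSION + timedelta(days=2 * index)
    discharge = admission + timedelta(hours=stay_h)

    chronic = bool(rng.random() < cfg.chronic_prevalence)
    excluded = bool(rng.random() < cfg.inr_exclusion_prevalence)
    on_ecmo = bool(rng.random() < cfg.ecmo_prevalence)
    affected = bool(rng.random() < cfg.episode_prevalence)

    diagnoses = []
    if chronic:
        diagnoses.append(DiagnosisRecord(pid, "C91.0"))
    if excluded:
        diagnoses.append(DiagnosisRecord(pid, "D66"))

    procedures = []
    if on_ecmo:
        e_start = float(rng.uniform(0.0, stay_h / 2.0))
        e_dur = min(float(rng.uniform(12.0, 72.0)), stay_h - e_start)
        procedures.append(
            ProcedureEpisode(
                pid,
                _round_minute(admission, e_start),
                _round_minute(admission, e_start + e_dur),
            )
        )

    # injected episodes: disjoint, ordered, inside the stay
    episodes: list[_Episode] = []
    n_injected = 0
    if affected:
        lo, hi = cfg.episodes_per_affected
        n_target = int(rng.integers(lo, hi + 1))
        dur_lo, dur_hi = cfg.episode_duration_hours
        # the first episode always fits the stay (dysfunction can begin
        # at admission in short stays), so the affected-patient fraction
        # tracks the configured prevalence; later episodes are dropped
        # when the stay has no room left
        cursor = min(cfg.episode_earliest_start_hours, stay_h - dur_lo)
        for k in range(n_target):
            if k == 0:
                dur = float(rng.uniform(dur_lo, min(dur_hi, stay_h - cursor)))
            else:
                dur = float(rng.uniform(dur_lo, dur_hi))
            latest = stay_h - dur
            if latest < cursor:
                break
            start = float(rng.uniform(cursor, latest))
            kind = str(rng.choice(["plt", "inr", "both"]))
            peak = float(rng.uniform(*cfg.inr_peak_range))
            episodes.append(_Episode(start, dur, kind, peak))
            cursor = start + dur + cfg.min_episode_gap_hours
        n_injected = len(episodes)

    plt_base = float(rng.uniform(*cfg.baseline_plt_range))
    inr_base = float(rng.uniform(*cfg.inr_baseline_range))
    plt_nadir = cfg.plt_nadir_fraction * plt_base

    def latent(analyte: Analyte, t_h: float) -> float:
        if analyte is Analyte.PLT:
            for ep in episodes:
                if ep.kind in ("plt", "both"):
                    v = _trapezoid(t_h, ep, plt_base, plt_nadir)
                    if v is not None:
                        return v
            return plt_base
        for ep in episodes:
            if ep.kind in ("inr", "both"):
                v = _trapezoid(t_h, ep, inr_base, ep.inr_peak)
                if v is not None:
                    return v
        return inr_base

    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0
    observations: list[LabObservation] = []
    for analyte, interval in (
        (Analyte.PLT, cfg.plt_sampling_hours),
        (Analyte.INR, cfg.inr_sampling_hours),
    ):
        for t_h in _sample_times(rng, stay_h, interval):
            v = latent(analyte, t_h)
            if sigma > 0:
                v *= math.exp(float(rng.normal(0.0, sigma)) - sigma**2 / 2.0)
            if cfg.error_spike_rate > 0 and rng.random() < cfg.error_spike_rate:
                v *= float(rng.choice([0.3, 2.5]))
            if analyte is Analyte.PLT:
                v = max(1.0, round(v))
            else:
                v = max(0.01, round(v, 2))
            observations.append(
                LabObservation(pid, analyte, v, _round_minute(admission, t_h))
            )
    observations.sort(key=lambda o: o.timestamp)

    # ground truth: latent-curve threshold crossings under the same rules
    plt_threshold = rules.plt_min
    if chronic:
        plt_threshold = max(plt_threshold, (1.0 - rules.decline_fraction) * plt_base)
    crossings: list[tuple[float, float]] = []
    n_undetectable = 0
    for ep in episodes:
        hit = False
        if ep.kind in ("plt", "both"):
            c = _crossing(ep, plt_base, plt_nadir, plt_threshold, below=True)
            if c:
                crossings.append(c)
                hit = True
        if ep.kind in ("inr", "both") and not excluded:
            c = _crossing(ep, inr_base, ep.inr_peak, rules.inr_max, below=False)
            if c:
                crossings.append(c)
                hit = True
        if not hit:
            n_undetectable += 1

    truth = [
        ReferenceEpisode(
            pid,
            max(admission, _round_minute(admission, s)),
            min(discharge, _round_minute(admission, e, up=True)),
        )
        for s, e in merge_touching(crossings)
    ]

    patient = PatientRecord(
        pid, age, admission, discharge,
        tuple(observations), tuple(diagnoses), tuple(procedures),
    )
    return patient, truth, n_injected, n_undetectable


def generate_cohort(config: SimConfig, rule_config: Optional[RuleConfig] = None) -> SyntheticCohort:
    """Generate a reproducible cohort with injected ground-truth episodes."""
    rules = rule_config or RuleConfig()
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients: list[PatientRecord] = []
    truth: list[ReferenceEpisode] = []
    injected: dict[str, int] = {}
    undetectable = 0
    for i, ss in enumerate(children):
        patient, t, n_inj, n_und = _generate_patient(i, ss, config, rules)
        patients.append(patient)
        truth.extend(t)
        injected[patient.patient_id] = n_inj
        undetectable += n_und
    if undetectable:
        logger.warning(
            "%d injected episode(s) never cross the rule thresholds "
            "(nadir/peak inside the normal range) and carry no ground truth",
            undetectable,
        )
    return SyntheticCohort(
        patients=patients,
        truth=truth,
        provenance={
            "sim_config": asdict(config),
            "seed": config.seed,
            "injected_episodes": injected,
            "undetectable_injections": undetectable,
        },
    )


def degrade_sampling(cohort: SyntheticCohort, factor: float) -> SyntheticCohort:
    """Thin observations so effective sampling intervals grow by ``factor``.

    Keeps, per patient and analyte, roughly every ``factor``-th
    observation (deterministically by index). Truth episodes are
    unchanged, so the effect of coarser sampling on detection accuracy
    is directly measurable.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    new_patients = []
    for p in cohort.patients:
        kept: list[LabObservation] = []
        for analyte in Analyte:
            obs = [o for o in p.observations if o.analyte is analyte]
            kept.extend(
                o
                for i, o in enumerate(obs)
                if i == 0 or math.floor(i / factor) != math.floor((i - 1) / factor)
            )
        kept.sort(key=lambda o: o.timestamp)
        new_patients.append(dc_replace(p, observations=tuple(kept)))
    provenance = dict(cohort.provenance)
    provenance["sampling_degradation_factor"] = factor
    return SyntheticCohort(new_patients, list(cohort.truth), provenance)


__all__ = ["SimConfig", "SyntheticCohort", "generate_cohort", "degrade_sampling"]
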