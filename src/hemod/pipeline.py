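"""End-to-end helpers: detect over a cohort and evaluate against truth."""

from __future__ import annotations

from datetime import datetime
from typing import Optional, Sequence

from . import evaluation, rules, simulate
from .evaluation import AccuracyResult, EvalConfig
from .types import EvaluationBlock, ODEpisode, PatientRecord, ReferenceEpisode, RuleConfig


def detect_cohort(
    patients: Sequence[PatientRecord], config: Optional[RuleConfig] = None
) -> list[ODEpisode]:
    """Run the rule engine over every patient of a cohort."""
    config = config or RuleConfig()
    return [ep for p in patients for ep in rules.detect_hematologic_od(p, config)]


def evaluate_episode_sets(
    patients: Sequence[PatientRecord] | Sequence[tuple[str, float, datetime, datetime]],
    cdss_episodes: Sequence,
    ref_episodes: Sequence,
    config: Optional[EvalConfig] = None,
) -> tuple[list[EvaluationBlock], AccuracyResult]:
    """Build labeled blocks for every patient and estimate accuracy.

    ``patients`` may be PatientRecords or raw (id, age, admission,
    discharge) rows; episode sequences may be ODEpisode/ReferenceEpisode
    objects or anything with patient_id/start/end.
    """
    config = config or EvalConfig()
    records: list[PatientRecord] = [
        p if isinstance(p, PatientRecord) else PatientRecord(p[0], p[1], p[2], p[3])
        for p in patients
    ]
    blocks: list[EvaluationBlock] = []
    for p in records:
        cdss = [(e.start, e.end) for e in cdss_episodes if e.patient_id == p.patient_id]
        ref = [(e.start, e.end) for e in ref_episodes if e.patient_id == p.patient_id]
        blocks.extend(evaluation.build_blocks(p, cdss, ref, config))
    return blocks, evaluation.diagnostic_accuracy(blocks)


def run_pipeline(
    sim_config: simulate.SimConfig,
    rule_config: Optional[RuleConfig] = None,
    eval_config: Optional[EvalConfig] = None,
) -> tuple[simulate.SyntheticCohort, list[ODEpisode], list[EvaluationBlock], AccuracyResult]:
    """simulate -> detect -> evaluate, returning every intermediate."""
    rule_config = rule_config or RuleConfig()
    cohort = simulate.generate_cohort(sim_config, rule_config)
    episodes = detect_cohort(cohort.patients, rule_config)
    blocks, result = evaluate_episode_sets(cohort.patients, episodes, cohort.truth, eval_config)
    return cohort, episodes, blocks, result


__all__ = ["detect_cohort", "evaluate_episode_sets", "run_pipeline"]
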