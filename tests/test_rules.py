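"""Unit and property tests for the rule engine."""

from __future__ import annotations

from datetime import timedelta

import pytest
from hypothesis import given, settings, strategies as st

from conftest import T0, brute_force_episodes, h, make_patient
from hemod import rules
from hemod.types import (
    AlarmCategory,
    AlarmCriterion,
    AlarmEvent,
    Analyte,
    DiagnosisRecord,
    LabObservation,
    NormRange,
    ODCause,
    ProcedureEpisode,
    RuleConfig,
)


class TestNormModel:
    def test_default_norm_ranges(self, default_config):
        plt = rules.specify_norm(Analyte.PLT, default_config)
        assert (plt.minimum, plt.maximum) == (80_000, 1_000_000)
        inr = rules.specify_norm(Analyte.INR, default_config)
        assert (inr.minimum, inr.maximum) == (0.5, 2.0)

    def test_config_passthrough(self):
        cfg = RuleConfig(plt_min=90_000)
        assert rules.specify_norm(Analyte.PLT, cfg).minimum == 90_000

    def test_unknown_analyte_rejected(self, default_config):
        with pytest.raises(ValueError, match="analyte"):
            rules.specify_norm("sodium", default_config)  # type: ignore[arg-type]

    @pytest.mark.parametrize(
        "analyte,value,expected",
        [
            (Analyte.PLT, 70_000, AlarmCategory.TOO_LOW),
            (Analyte.PLT, 80_000, AlarmCategory.NORMAL),  # strict "<"
            (Analyte.PLT, 200_000, AlarmCategory.NORMAL),
            (Analyte.PLT, 1_200_000, AlarmCategory.TOO_HIGH),
            (Analyte.INR, 2.0, AlarmCategory.NORMAL),  # strict ">"
            (Analyte.INR, 2.1, AlarmCategory.TOO_HIGH),
            (Analyte.INR, 0.4, AlarmCategory.TOO_LOW),
        ],
    )
    def test_evaluate_observation(self, default_config, analyte, value, expected):
        obs = LabObservation("P1", analyte, value, h(1))
        norm = rules.specify_norm(analyte, default_config)
        assert rules.evaluate_observation(obs, norm) is expected

    def test_analyte_mismatch_rejected(self, default_config):
        obs = LabObservation("P1", Analyte.PLT, 100_000, h(1))
        with pytest.raises(ValueError, match="mismatch"):
            rules.evaluate_observation(obs, rules.specify_norm(Analyte.INR, default_config))


class TestBaselineAndGating:
    def test_baseline_is_earliest_platelet(self):
        p = make_patient(plt=[(1, 200_000), (6, 150_000)])
        assert rules.baseline_platelet(p).value == 200_000

    def test_baseline_absent_without_platelets(self):
        p = make_patient(inr=[(1, 1.0)])
        assert rules.baseline_platelet(p) is None

    def test_baseline_at_admission_instant(self):
        p = make_patient(plt=[(0, 300_000)])
        assert rules.baseline_platelet(p).timestamp == T0

    @pytest.mark.parametrize(
        "codes,chronic_set,prefix,expected",
        [
            (("C91.0",), ("C91.0",), False, True),
            ((), ("C91.0",), False, False),
            (("J45.9",), ("C91.0",), False, False),
            (("C91.1",), ("C91",), True, True),
            (("C91.1",), ("C91",), False, False),
        ],
    )
    def test_chronic_rule_membership(self, codes, chronic_set, prefix, expected):
        p = make_patient(diagnoses=[DiagnosisRecord("P1", c) for c in codes])
        cfg = RuleConfig(chronic_hemonc_codes=chronic_set, code_prefix_match=prefix)
        assert rules.applies_chronic_rule(p, cfg) is expected

    def test_inr_exclusion_membership(self):
        p = make_patient(diagnoses=[DiagnosisRecord("P1", "D66")])
        assert rules.inr_excluded(p, RuleConfig()) is True
        assert rules.inr_excluded(p, RuleConfig(inr_exclusion_codes=())) is False
        assert rules.inr_excluded(make_patient(), RuleConfig()) is False


class TestEcmoWindows:
    def test_default_extension(self, default_config):
        p = make_patient(procedures=[ProcedureEpisode("P1", h(10), h(20))])
        assert rules.extended_ecmo_windows(p, default_config) == [(h(8), h(32))]

    def test_no_ecmo_empty(self, default_config):
        assert rules.extended_ecmo_windows(make_patient(), default_config) == []

    def test_close_runs_merge_into_one_window(self, default_config):
        p = make_patient(
            stay_hours=72,
            procedures=[
                ProcedureEpisode("P1", h(2), h(12)),
                ProcedureEpisode("P1", h(13), h(20)),
            ],
        )
        assert rules.extended_ecmo_windows(p, default_config) == [(h(0), h(32))]


class TestAlarmEvents:
    def test_abnormal_event_closes_at_next_normal(self, default_config):
        p = make_patient(plt=[(1, 70_000), (10, 120_000)], stay_hours=48)
        events = rules.raw_alarm_events(p, default_config)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start, ev.end) == (h(1), h(10))
        assert ev.category is AlarmCategory.TOO_LOW
        assert ev.criterion is AlarmCriterion.ABSOLUTE

    def test_open_event_runs_to_discharge(self, default_config):
        p = make_patient(plt=[(1, 70_000)], stay_hours=48)
        (ev,) = rules.raw_alarm_events(p, default_config)
        assert ev.end == h(48)

    def test_relative_decline_fires_only_for_chronic_patients(self, default_config):
        obs = [(1, 200_000), (12, 90_000)]
        chronic = make_patient(
            plt=obs, diagnoses=[DiagnosisRecord("P1", "C91.0")]
        )
        events = rules.raw_alarm_events(chronic, default_config)
        assert [e.criterion for e in events] == [AlarmCriterion.RELATIVE_DECLINE]
        assert events[0].category is AlarmCategory.TOO_LOW
        # same values without the chronic diagnosis: 90,000 >= 80,000, no alarm
        assert rules.raw_alarm_events(make_patient(plt=obs), default_config) == []

    def test_baseline_observation_never_triggers_relative_rule(self, default_config):
        # a chronic patient whose first value is already low relative to
        # nothing: only the absolute rule may fire on it
        p = make_patient(
            plt=[(1, 90_000), (12, 90_000)],
            diagnoses=[DiagnosisRecord("P1", "C91.0")],
        )
        assert rules.raw_alarm_events(p, default_config) == []

    def test_decline_boundary_is_inclusive(self, default_config):
        p = make_patient(
            plt=[(1, 200_000), (12, 100_000)],
            diagnoses=[DiagnosisRecord("P1", "C91.0")],
        )
        (ev,) = rules.raw_alarm_events(p, default_config)
        assert ev.criterion is AlarmCriterion.RELATIVE_DECLINE

    def test_merge_same_group_overlap(self):
        a = AlarmEvent("P1", Analyte.PLT, AlarmCategory.TOO_LOW, AlarmCriterion.ABSOLUTE, h(0), h(5))
        b = AlarmEvent("P1", Analyte.PLT, AlarmCategory.TOO_LOW, AlarmCriterion.ABSOLUTE, h(4), h(8))
        merged = rules.merge_alarm_events([a, b])
        assert [(e.start, e.end) for e in merged] == [(h(0), h(8))]

    def test_merge_keeps_distinct_parameter_types_apart(self):
        a = AlarmEvent("P1", Analyte.PLT, AlarmCategory.TOO_LOW, AlarmCriterion.ABSOLUTE, h(0), h(5))
        b = AlarmEvent("P1", Analyte.INR, AlarmCategory.TOO_HIGH, AlarmCriterion.ABSOLUTE, h(4), h(8))
        assert len(rules.merge_alarm_events([a, b])) == 2

    def test_merge_empty(self):
        assert rules.merge_alarm_events([]) == []


class TestDetection:
    def test_alarm_inside_ecmo_window_suppressed(self, default_config):
        p = make_patient(
            plt=[(4, 60_000), (10, 150_000)],
            procedures=[ProcedureEpisode("P1", h(4), h(8))],  # window [2, 20]
        )
        assert rules.detect_hematologic_od(p, default_config) == []
        assert rules.ecmo_suppressed_intervals(p, default_config) == [(h(4), h(10))]

    def test_partial_ecmo_overlap_truncates(self, default_config):
        p = make_patient(
            plt=[(4, 60_000), (30, 150_000)],
            stay_hours=48,
            procedures=[ProcedureEpisode("P1", h(4), h(8))],  # window [2, 20]
        )
        (ep,) = rules.detect_hematologic_od(p, default_config)
        assert (ep.start, ep.end, ep.cause) == (h(20), h(30), ODCause.PLATELETS)

    def test_overlapping_plt_and_inr_become_both(self, default_config):
        p = make_patient(
            plt=[(0, 60_000), (6, 150_000)],
            inr=[(5, 2.5), (9, 1.2)],
            stay_hours=48,
        )
        (ep,) = rules.detect_hematologic_od(p, default_config)
        assert (ep.start, ep.end, ep.cause) == (h(0), h(9), ODCause.BOTH)

    def test_touching_intervals_concatenate(self, default_config):
        p = make_patient(
            plt=[(0, 60_000), (6, 150_000)],
            inr=[(6, 2.5), (9, 1.2)],
            stay_hours=48,
        )
        (ep,) = rules.detect_hematologic_od(p, default_config)
        assert ep.cause is ODCause.BOTH

    def test_inr_exclusion_drops_inr_episodes(self, default_config):
        p = make_patient(
            inr=[(5, 2.5), (9, 1.2)],
            diagnoses=[DiagnosisRecord("P1", "D66")],
        )
        assert rules.detect_hematologic_od(p, default_config) == []
        # exclusion leaves platelet-caused episodes intact
        p2 = make_patient(
            plt=[(1, 60_000), (6, 150_000)],
            inr=[(5, 2.5), (9, 1.2)],
            diagnoses=[DiagnosisRecord("P1", "D66")],
        )
        (ep,) = rules.detect_hematologic_od(p2, default_config)
        assert (ep.start, ep.end, ep.cause) == (h(1), h(6), ODCause.PLATELETS)

    def test_high_platelets_and_low_inr_never_cause_dysfunction(self, default_config):
        p = make_patient(plt=[(1, 1_500_000)], inr=[(2, 0.3)])
        assert rules.detect_hematologic_od(p, default_config) == []
        assert len(rules.raw_alarm_events(p, default_config)) == 2  # alarms exist


# -- property tests ---------------------------------------------------------

obs_series = st.lists(
    st.tuples(
        st.floats(min_value=0.0, max_value=47.9),
        st.floats(min_value=1_000, max_value=500_000),
    ),
    max_size=12,
)
inr_series = st.lists(
    st.tuples(
        st.floats(min_value=0.0, max_value=47.9),
        st.floats(min_value=0.6, max_value=4.0),
    ),
    max_size=12,
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(plt=obs_series, inr=inr_series)
def test_detection_is_deterministic_and_matches_oracle(plt, inr):
    """Confounder-free detection equals brute-force run reconstruction."""
    # drop duplicate timestamps (minute resolution would collapse them)
    plt = list({round(t, 2): v for t, v in plt}.items())
    inr = list({round(t, 2): v for t, v in inr}.items())
    p = make_patient(plt=plt, inr=inr, stay_hours=48)
    cfg = RuleConfig()
    got = rules.detect_hematologic_od(p, cfg)
    assert got == rules.detect_hematologic_od(p, cfg)  # determinism
    expected = brute_force_episodes(p, cfg)
    assert [(e.start, e.end, e.cause) for e in got] == expected


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    plt=obs_series,
    lower=st.floats(min_value=20_000, max_value=79_000),
)
def test_lowering_plt_min_never_lengthens_episodes(plt, lower):
    """A more permissive platelet threshold cannot increase episode time."""
    plt = list({round(t, 2): v for t, v in plt}.items())
    p = make_patient(plt=plt, stay_hours=48)

    def total(cfg):
        eps = rules.detect_hematologic_od(p, cfg)
        return sum((e.end - e.start for e in eps), timedelta())

    assert total(RuleConfig(plt_min=lower)) <= total(RuleConfig())


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    inr=inr_series,
    higher=st.floats(min_value=2.1, max_value=5.0),
)
def test_raising_inr_max_never_lengthens_episodes(inr, higher):
    inr = list({round(t, 2): v for t, v in inr}.items())
    p = make_patient(inr=inr, stay_hours=48)

    def total(cfg):
        eps = rules.detect_hematologic_od(p, cfg)
        return sum((e.end - e.start for e in eps), timedelta())

    assert total(RuleConfig(inr_max=higher)) <= total(RuleConfig())


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    plt=obs_series,
    ecmo_start=st.floats(min_value=0, max_value=40),
    ecmo_len=st.floats(min_value=0, max_value=24),
)
def test_ecmo_suppression_is_exact(plt, ecmo_start, ecmo_len):
    """Episode time inside extended ECMO windows is exactly zero."""
    from hemod.intervals import intersect, total_duration

    plt = list({round(t, 2): v for t, v in plt}.items())
    p = make_patient(
        plt=plt,
        stay_hours=48,
        procedures=[ProcedureEpisode("P1", h(ecmo_start), h(min(48, ecmo_start + ecmo_len)))],
    )
    cfg = RuleConfig()
    eps = rules.detect_hematologic_od(p, cfg)
    windows = rules.extended_ecmo_windows(p, cfg)
    overlap = intersect([(e.start, e.end) for e in eps], windows)
    assert total_duration(overlap) in (0, timedelta(0))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(plt=obs_series, inr=inr_series)
def test_both_episodes_are_unions_of_contributing_intervals(plt, inr):
    plt = list({round(t, 2): v for t, v in plt}.items())
    inr = list({round(t, 2): v for t, v in inr}.items())
    p = make_patient(plt=plt, inr=inr, stay_hours=48)
    cfg = RuleConfig()
    merged = rules.merge_alarm_events(rules.raw_alarm_events(p, cfg))
    contributing = [
        (e.start, e.end)
        for e in merged
        if (e.analyte is Analyte.PLT and e.category is AlarmCategory.TOO_LOW)
        or (e.analyte is Analyte.INR and e.category is AlarmCategory.TOO_HIGH)
    ]
    for ep in rules.detect_hematologic_od(p, cfg):
        if ep.cause is ODCause.BOTH:
            inside = [(s, e) for s, e in contributing if ep.start <= s and e <= ep.end]
            from hemod.intervals import merge_touching

            assert merge_touching(inside) == [(ep.start, ep.end)]
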