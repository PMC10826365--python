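import numpy as np
import pytest

from heatlimits import trials
from heatlimits.calorimetry import MetabolicSample, Subject
from heatlimits.inflection import ProtocolError, Trace
from heatlimits.synthdata import TraceSpec, generate_trace
from heatlimits.trials import (
    ConfigError,
    HeatBalanceParams,
    RampSchedule,
    analyze_trial,
    analyze_trials,
    build_schedule,
    estimate_censored_limit,
    last_completed_stage,
)


class TestRampSchedule:
    def test_equilibration_value(self):
        s = build_schedule({"mode": "P_crit", "fixed_value": 36, "start_value": 20})
        assert s.env_at(29.0) == 20.0

    def test_step_at_interval_start(self):
        s = build_schedule({"mode": "P_crit", "fixed_value": 36, "start_value": 20})
        assert s.env_at(36.0) == 22.0
        assert s.env_at(30.0) == 21.0
        # half-open step convention: the boundary sample starts the next stage
        assert s.env_at(34.9) == 21.0
        assert s.env_at(35.0) == 22.0

    def test_tcrit_ramp_reach(self):
        s = build_schedule({"mode": "T_crit", "fixed_value": 16, "start_value": 36})
        assert s.env_at(99.9) == 50.0
        assert s.env_at(100.0) == 51.0

    def test_unknown_mode(self):
        with pytest.raises(ConfigError, match="mode"):
            build_schedule({"mode": "X_crit", "fixed_value": 36, "start_value": 20})

    def test_missing_key(self):
        with pytest.raises(ConfigError, match="start_value"):
            build_schedule({"mode": "P_crit", "fixed_value": 36})

    def test_time_env_exceeds(self):
        s = RampSchedule(mode="P_crit", fixed_value=40.0, start_value=21.0)
        t = s.time_env_exceeds(29.0)
        assert s.env_at(t) > 29.0
        assert s.env_at(t - 0.1) <= 29.0


class TestAnalyzeTrial:
    def test_fig2_style_trial(self, pcrit_schedule):
        spec = TraceSpec(schedule=pcrit_schedule, true_critical=29.0,
                         noise_sd=0.05, ar1=0.8, seed=11)
        res = analyze_trial(generate_trace(spec))
        assert not res.censored
        assert res.critical_value == pytest.approx(29.0, abs=1.0)
        assert res.mode == "P_crit"

    def test_locus_axis_roles(self, pcrit_schedule, noise_free_record):
        res = analyze_trial(noise_free_record)
        assert res.t_db == pcrit_schedule.fixed_value
        assert res.p_a == res.critical_value
        assert 0 < res.rh <= 100

        tsched = RampSchedule(mode="T_crit", fixed_value=16.0, start_value=34.0)
        tres = analyze_trial(generate_trace(
            TraceSpec(schedule=tsched, true_critical=41.0, noise_sd=0.0)))
        assert tres.p_a == 16.0
        assert tres.t_db == tres.critical_value
        assert 0 < tres.rh <= 100

    def test_no_inflection_censored(self, pcrit_schedule):
        spec = TraceSpec(schedule=pcrit_schedule, true_critical=None,
                         noise_sd=0.0, censored_duration=125.0)
        res = analyze_trial(generate_trace(spec), estimate_censored=False)
        assert res.censored
        assert res.estimation == "censored"
        # censored value is the last fully completed stage
        assert res.critical_value == pytest.approx(
            last_completed_stage(generate_trace(spec).trace, pcrit_schedule))

    def test_short_trace_rejected(self, pcrit_schedule):
        t = np.arange(0.0, 41.0)
        tr = Trace(t=t, t_gi=np.full_like(t, 37.0),
                   env=pcrit_schedule.env_at(t), fixed=40.0)
        rec = trials.TrialRecord("t", "s", "Rest", pcrit_schedule, tr)
        with pytest.raises(ProtocolError, match="shorter"):
            analyze_trial(rec)

    def test_batch_order_preserved(self, pcrit_schedule):
        recs = [generate_trace(
            TraceSpec(schedule=pcrit_schedule, true_critical=29.0,
                      noise_sd=0.02, seed=s), trial_id=f"T{s}")
            for s in range(4)]
        out = analyze_trials(recs)
        assert [r.trial_id for r in out] == [f"T{s}" for s in range(4)]

    def test_calorimetry_attached(self, noise_free_record):
        subject = Subject(id="S1", age_group="older", height=1.68, mass=73.4)
        noise_free_record.metabolic = (
            MetabolicSample(0.43, 0.85, 5), MetabolicSample(0.43, 0.85, 60))
        res = analyze_trial(noise_free_record, subject)
        assert res.m_net == pytest.approx(80.1, abs=0.5)
        assert res.mets == pytest.approx(1.67, abs=0.02)


class TestLastCompletedStage:
    def test_final_partial_stage_excluded(self, pcrit_schedule):
        # trace ends 2 min into the 30-mmHg stage → last completed stage is 29
        spec = TraceSpec(schedule=pcrit_schedule, true_critical=None, noise_sd=0.0,
                         censored_duration=72.0)
        tr = generate_trace(spec).trace
        assert last_completed_stage(tr, pcrit_schedule) == 29.0

    def test_final_full_stage_included(self, pcrit_schedule):
        spec = TraceSpec(schedule=pcrit_schedule, true_critical=None, noise_sd=0.0,
                         censored_duration=75.0)
        tr = generate_trace(spec).trace
        assert last_completed_stage(tr, pcrit_schedule) == 30.0


class TestEstimateCensoredLimit:
    HB = HeatBalanceParams()

    def test_clamped_to_window(self):
        for m_net in (40.0, 60.0, 100.0):
            p = estimate_censored_limit(m_net, 34.0, 28.0, self.HB)
            assert 28.0 <= p <= 33.0

    def test_zero_evaporation_upper_clamp(self, caplog):
        # dry loss ≥ M_net → no evaporation required → clamp upper bound
        hb = HeatBalanceParams(t_sk=36.0, h_c=20.0, h_r=20.0)
        with caplog.at_level("WARNING"):
            p = estimate_censored_limit(40.0, 34.0, 28.0, hb)
        assert p == 33.0
        assert "trivially maintained" in caplog.text

    def test_heavily_negative_estimate_clamps_low(self):
        # hand arithmetic: e_req = 48 − 9·2 = 30; P_est = P_sat(36) − 30/0.42 ≈ −27
        hb = HeatBalanceParams(t_sk=36.0, h_c=4.3, h_r=4.7, h_e=0.42 / 0.65, w_max=0.65)
        p = estimate_censored_limit(48.0, 34.0, 28.0, hb)
        assert p == 28.0

    def test_monotone_decreasing_in_m_net_and_t_db(self):
        # parameters chosen so the raw estimates land inside the clamp window
        hb = HeatBalanceParams()
        base = estimate_censored_limit(50.0, 34.0, 36.0, hb)
        assert estimate_censored_limit(60.0, 34.0, 36.0, hb) < base
        assert estimate_censored_limit(50.0, 35.0, 36.0, hb) < base

    def test_routed_for_34C_pcrit_only(self):
        sched34 = RampSchedule(mode="P_crit", fixed_value=34.0, start_value=20.0)
        sched36 = RampSchedule(mode="P_crit", fixed_value=36.0, start_value=20.0)
        subject = Subject(id="S1", age_group="older", height=1.68, mass=73.4)
        met = (MetabolicSample(0.27, 0.85, 5),)
        for sched, expected in [(sched34, "heat_balance_estimated"),
                                (sched36, "censored")]:
            rec = generate_trace(TraceSpec(schedule=sched, true_critical=None,
                                           noise_sd=0.0))
            rec.metabolic = met
            res = analyze_trial(rec, subject)
            assert res.censored
            assert res.estimation == expected


class TestHeatBalanceParams:
    def test_lewis_default(self):
        hb = HeatBalanceParams(h_c=4.3)
        assert hb.h_e == pytest.approx(2.2 * 4.3)

    @pytest.mark.parametrize("kw", [{"w_max": 1.2}, {"h_c": -1.0}, {"w_max": 0.0}])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            HeatBalanceParams(**kw)
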