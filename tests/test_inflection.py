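import numpy as np
import pytest

from heatlimits import inflection
from heatlimits.inflection import (
    InflectionFit,
    ProtocolError,
    Trace,
    critical_env_value,
    detect_inflection,
    tgi_rate_of_change,
)

def piecewise_trace(bp=60.0, slope_below=0.0, slope_above=0.7, t_end=120.0,
                    noise_sd=0.0, seed=0, base=37.0):
    """Flat/drift then linear-rise trace; slopes in °C·h⁻¹."""
    t = np.arange(0.0, t_end + 0.5)
    mean = base + slope_below / 60 * np.clip(t, None, bp) + \
        slope_above / 60 * np.maximum(t - bp, 0.0)
    rng = np.random.default_rng(seed)
    y = mean + (rng.normal(0, noise_sd, len(t)) if noise_sd else 0.0)
    return Trace(t=t, t_gi=y, env=np.full_like(t, 20.0), fixed=40.0)


class TestTraceValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            Trace(t=[0, 1, 2], t_gi=[37, 37], env=[20, 20, 20], fixed=40.0)

    def test_non_monotone_time(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trace(t=[0, 2, 1], t_gi=[37, 37, 37], env=[20, 20, 20], fixed=40.0)

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError, match="≤ 1 min"):
            Trace(t=[0, 2, 4], t_gi=[37, 37, 37], env=[20, 20, 20], fixed=40.0)

    def test_physiological_screen_flags(self, caplog):
        t = np.arange(3.0)
        with caplog.at_level("WARNING"):
            tr = Trace(t=t, t_gi=[37.0, 43.0, 37.0], env=[20.0] * 3, fixed=40.0)
        assert tr.flags.sum() == 1


class TestDetectInflection:
    def test_noise_free_exact(self):
        tr = piecewise_trace(bp=60.0)
        fit = detect_inflection(tr)
        assert fit.detected
        assert abs(fit.breakpoint_time - 60.0) <= 1.0
        assert fit.slope_below == pytest.approx(0.0, abs=1e-8)
        assert fit.slope_above == pytest.approx(0.7, abs=1e-8)
        assert fit.sse == pytest.approx(0.0, abs=1e-16)

    def test_strictly_linear_not_detected(self):
        t = np.arange(0.0, 121.0)
        tr = Trace(t=t, t_gi=37.0 + 0.005 * t, env=np.full_like(t, 20.0), fixed=40.0)
        assert not detect_inflection(tr).detected

    def test_constant_not_detected(self):
        t = np.arange(0.0, 121.0)
        tr = Trace(t=t, t_gi=np.full_like(t, 37.0), env=np.full_like(t, 20.0), fixed=40.0)
        assert not detect_inflection(tr).detected

    def test_too_short_raises(self):
        tr = piecewise_trace(t_end=50.0)
        with pytest.raises(ProtocolError, match="min"):
            detect_inflection(tr)

    def test_white_noise_recovery(self):
        # regression guard at 85%: measured rate on these 200 seeds is 89.5%,
        # i.e. within Monte-Carlo error of the nominal 90% design point
        hits = 0
        for seed in range(200):
            fit = detect_inflection(piecewise_trace(noise_sd=0.05, seed=seed))
            hits += fit.detected and abs(fit.breakpoint_time - 60.0) <= 5.0
        assert hits >= 170

    def test_noise_robustness_monotone(self):
        rmse = []
        for sd in (0.01, 0.05, 0.1):
            errs = []
            for seed in range(60):
                fit = detect_inflection(piecewise_trace(noise_sd=sd, seed=seed))
                if fit.detected:
                    errs.append(fit.breakpoint_time - 60.0)
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        assert rmse[0] <= rmse[1] <= rmse[2]

    def test_slope_gap_positive_when_detected(self, pcrit_schedule, noisy_record_factory):
        for seed in range(30):
            rec = noisy_record_factory(pcrit_schedule, seed)
            fit = detect_inflection(rec.trace)
            if fit.detected:
                assert fit.slope_above > fit.slope_below

    def test_exhaustiveness_vs_independent_grid(self):
        """Returned SSE must match an independently-coded per-candidate fit."""
        tr = piecewise_trace(noise_sd=0.05, seed=3)
        fit = detect_inflection(tr)
        mask = tr.t >= 45.0
        tt, yy = tr.t[mask], tr.t_gi[mask]
        best = np.inf
        for c in tt[(tt <= tr.t[-1] - 10) & (tt > tt[0]) & (tt < tt[-1])]:
            # independent hinge SSE via explicit normal equations on centred basis
            X = np.stack([np.ones_like(tt), tt - c, np.where(tt > c, tt - c, 0.0)], 1)
            beta = np.linalg.solve(X.T @ X, X.T @ yy)
            best = min(best, float(np.sum((yy - X @ beta) ** 2)))
        assert fit.sse == pytest.approx(best, rel=1e-9)

    def test_free_intercept_variant(self):
        tr = piecewise_trace(noise_sd=0.05, seed=1)
        fit = detect_inflection(tr, free_intercept=True)
        assert fit.detected
        assert abs(fit.breakpoint_time - 60.0) <= 10.0


class TestCriticalEnvValue:
    def test_constant_window(self):
        t = np.arange(0.0, 121.0)
        tr = Trace(t=t, t_gi=np.full_like(t, 37.0), env=np.full_like(t, 16.0), fixed=36.0)
        fit = InflectionFit(True, 70.0, 0.1, 0.7, 0.0, 45.0)
        assert critical_env_value(tr, fit) == 16.0

    def test_step_straddle(self):
        # window [68, 70) holds one sample at 28 and one at 29
        t = np.arange(0.0, 121.0)
        env = np.where(t < 69, 28.0, 29.0)
        tr = Trace(t=t, t_gi=np.full_like(t, 37.0), env=env, fixed=40.0)
        fit = InflectionFit(True, 70.0, 0.1, 0.7, 0.0, 45.0)
        assert critical_env_value(tr, fit) == pytest.approx(28.5)

    def test_full_step_window(self, noise_free_record):
        tr = noise_free_record.trace
        fit = inflection.detect_inflection(tr)
        # true inflection at 70 min; preceding 2 min lie in the 29-mmHg stage
        assert critical_env_value(tr, fit) == pytest.approx(29.0, abs=1.0)

    def test_undetected_raises(self, noise_free_record):
        fit = InflectionFit(False, 70.0, 0.1, 0.7, 0.0, 45.0)
        with pytest.raises(ValueError, match="censored"):
            critical_env_value(noise_free_record.trace, fit)


class TestRateOfChange:
    def test_noise_free_recovery(self):
        tr = piecewise_trace(bp=60.0, slope_below=0.1, slope_above=0.7)
        fit = detect_inflection(tr)
        below, above = tgi_rate_of_change(tr, fit)
        assert below == pytest.approx(0.10, abs=1e-8)
        assert above == pytest.approx(0.70, abs=1e-8)

    def test_two_point_window(self):
        tr = piecewise_trace(bp=60.0, slope_below=0.1, slope_above=0.7)
        fit = detect_inflection(tr)
        below, _ = tgi_rate_of_change(tr, fit, window=2.0)
        assert below == pytest.approx(0.10, abs=1e-8)

    def test_short_tail_uses_available_span(self, caplog):
        tr = piecewise_trace(bp=104.0, t_end=120.0, slope_below=0.1)
        fit = InflectionFit(True, 104.0, 0.1, 0.7, 0.0, 45.0)
        with caplog.at_level("WARNING"):
            _, above = tgi_rate_of_change(tr, fit, window=30.0)
        assert above == pytest.approx(0.7, abs=1e-6)

    def test_tail_below_5min_raises(self):
        tr = piecewise_trace(bp=117.0, t_end=120.0)
        fit = InflectionFit(True, 117.0, 0.0, 0.7, 0.0, 45.0)
        with pytest.raises(ValueError, match="≥ 5"):
            tgi_rate_of_change(tr, fit, window=10.0)
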