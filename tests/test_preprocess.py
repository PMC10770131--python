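"""Onset trim, 20-s splitting, l1 trend filtering, and degravitation."""

import numpy as np
import pytest
from scipy.signal import periodogram

from tremorkit.preprocess import (
    PreprocessConfig,
    degravitate,
    l1_trend_filter,
    l1_trend_objective,
    preprocess_session,
    segment_plan,
    split_long,
    trim_onset,
)
from tremorkit.protocol import DEFAULT_PROTOCOL, DEFAULT_REMOVED_STEPS
from tremorkit.session_io import AssessmentRecording
from tremorkit.synth import GeneratorConfig, generate_cohort

#: relative optimality slack of the interior-point solver's recovered primal
SOLVER_RTOL = 1e-4


class TestTrimOnset:
    def test_half_second_at_100hz_drops_50_samples(self):
        out = trim_onset(np.arange(1000.0), fs=100, trim_seconds=0.5)
        assert out.size == 950
        assert out[0] == 50.0

    def test_zero_trim_is_identity(self):
        x = np.arange(100.0)
        assert np.array_equal(trim_onset(x, 100, 0.0), x)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            trim_onset(np.arange(40.0), fs=100, trim_seconds=0.5)


class TestSplitLong:
    def test_default_protocol_yields_14_segments(self):
        plan = segment_plan(DEFAULT_PROTOCOL, frozenset())
        assert len(plan) == 14

    def test_default_step_removal_yields_11_segments(self):
        plan = segment_plan(DEFAULT_PROTOCOL, DEFAULT_REMOVED_STEPS)
        assert len(plan) == 11

    def test_ten_second_recording_passes_through(self):
        rec = AssessmentRecording("step2", "left", "acceleration", np.zeros((3, 1000)))
        assert split_long(rec) == [rec]

    def test_twenty_second_ramp_halves_are_continuous(self):
        ramp = np.tile(np.arange(2000.0), (3, 1))
        rec = AssessmentRecording("step1a", "left", "acceleration", ramp)
        first, second = split_long(rec)
        assert first.step_name == "step1a_1" and second.step_name == "step1a_2"
        assert first.samples[0, -1] + 1 == second.samples[0, 0]
        assert np.array_equal(
            np.hstack([first.samples, second.samples]), ramp
        )

    def test_unsupported_duration_rejected(self):
        rec = AssessmentRecording("odd", "left", "acceleration", np.zeros((3, 300)))
        with pytest.raises(ValueError, match="duration"):
            split_long(rec)


class TestL1TrendFilter:
    def test_zero_lambda_returns_input(self):
        x = np.random.default_rng(0).normal(size=200)
        assert np.array_equal(l1_trend_filter(x, 0.0), x)

    def test_linear_ramp_is_fixed_point(self):
        ramp = 0.01 * np.arange(500.0) - 1.0
        for lam in (1.0, 100.0, 1e4):
            assert np.abs(l1_trend_filter(ramp, lam) - ramp).max() < 1e-9

    def test_separates_line_from_sinusoid(self):
        # known generative decomposition: trend ~ line, residual ~ sinusoid
        rng = np.random.default_rng(42)
        n = 1000
        t = np.arange(n)
        line = 0.01 * t + 0.3
        sinusoid = np.sin(2 * np.pi * 4.0 * t / 100.0)
        x = line + sinusoid + rng.normal(0, 0.01, n)
        trend = l1_trend_filter(x, 1e4)
        assert np.abs(trend - line).max() < 0.1
        assert np.abs((x - trend) - sinusoid).max() < 0.1

    def test_objective_not_worse_than_raw_or_line(self):
        rng = np.random.default_rng(7)
        t = np.arange(600.0)
        for lam in (1.0, 100.0, 1e4):
            x = (rng.normal() + 0.02 * t + np.sin(2 * np.pi * rng.uniform(2, 8) * t / 100)
                 + rng.normal(0, 0.05, t.size))
            z = l1_trend_filter(x, lam)
            A = np.vstack([t, np.ones_like(t)]).T
            line = A @ np.linalg.lstsq(A, x, rcond=None)[0]
            bound = min(l1_trend_objective(x, x, lam), l1_trend_objective(x, line, lam))
            assert l1_trend_objective(x, z, lam) <= bound * (1 + SOLVER_RTOL) + 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            l1_trend_filter(np.array([1.0, np.nan, 2.0, 3.0]), 1.0)
        with pytest.raises(ValueError, match="3 samples"):
            l1_trend_filter(np.array([1.0, 2.0]), 1.0)
        with pytest.raises(ValueError):
            l1_trend_filter(np.ones(10), -1.0)


class TestDegravitate:
    def test_constant_series_maps_to_zero(self):
        out = degravitate(np.full(400, 0.81), 1e3)
        assert np.abs(out).max() < 1e-9

    def test_pure_linear_drift_maps_to_zero(self):
        out = degravitate(0.002 * np.arange(400.0) + 0.5, 1e3)
        assert np.abs(out).max() < 1e-8

    def test_decomposition_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.1, 500) + 0.01 * np.arange(500)
        trend = l1_trend_filter(x, 1e3)
        residual = degravitate(x, 1e3)
        assert np.allclose(residual + trend, x, rtol=0, atol=1e-12)

    def test_tremor_peak_frequency_survives_degravitation(self):
        t = np.arange(1000.0) / 100.0
        sinusoid = 0.1 * np.sin(2 * np.pi * 4.0 * t)
        drifted = sinusoid + 0.3 + 0.05 * t
        freqs, power = periodogram(degravitate(drifted, 1e4), fs=100.0)
        freqs0, power0 = periodogram(sinusoid, fs=100.0)
        assert freqs[np.argmax(power)] == freqs0[np.argmax(power0)] == 4.0


@pytest.fixture(scope="module")
def session():
    return generate_cohort(GeneratorConfig(n_pd=1, n_hc=0, n_dd=0, seed=5))[0]


class TestPreprocessSession:
    def test_default_pipeline_shape(self, session):
        segments = preprocess_session(session, PreprocessConfig(), DEFAULT_PROTOCOL)
        # 11 segments x 2 wrists x 2 sensors after default step removal
        assert len(segments) == 11 * 2 * 2
        lengths = {s.samples.shape[1] for s in segments}
        assert lengths == {950}  # 10 s - 0.5 s trim at 100 Hz

    def test_degravitated_acceleration_is_near_zero_mean(self, session):
        segments = preprocess_session(session, PreprocessConfig(), DEFAULT_PROTOCOL)
        acc = [s for s in segments if s.sensor == "acceleration"]
        means = np.array([np.abs(s.samples.mean(axis=1)).max() for s in acc])
        assert means.max() < 0.05  # gravity offset (~1 g) removed

    def test_rotation_channels_left_untouched_by_degravitation(self, session):
        raw = preprocess_session(
            session, PreprocessConfig(trend_lambda=0.0), DEFAULT_PROTOCOL
        )
        processed = preprocess_session(session, PreprocessConfig(), DEFAULT_PROTOCOL)
        raw_rot = {(s.name, s.wrist): s.samples for s in raw if s.sensor == "rotation"}
        for s in processed:
            if s.sensor == "rotation":
                assert np.array_equal(s.samples, raw_rot[(s.name, s.wrist)])

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            PreprocessConfig(trim_seconds=-0.1)
        with pytest.raises(ValueError):
            PreprocessConfig(trend_lambda=-1.0)
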