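"""VOR gain: differentiation, artifact rejection, peak statistic, recovery."""

import numpy as np
import pytest

from omnquant.gain import (GainConfig, compute_velocity, fish_gain,
                           peak_response, reject_artifacts)
from omnquant.stimulus import (PositionTrace, StimulusParams, build_session,
                               segment_steps, trapezoid_step)
from omnquant.synthetic import EyePlantParams, generate_session


def _trace(angle, fs=200.0):
    return PositionTrace(time=np.arange(len(angle)) / fs, angle=np.asarray(angle, float))


class TestComputeVelocity:
    def test_exact_on_linear_ramp(self):
        t = np.arange(200) / 200.0
        v = compute_velocity(_trace(7.0 * t), window_samples=5)
        np.testing.assert_allclose(v.velocity[3:-3], 7.0, atol=1e-9)

    def test_trapezoid_peak_velocity(self, default_stim):
        step = trapezoid_step(default_stim, 15.0)
        v = compute_velocity(step, window_samples=5)
        assert np.max(np.abs(v.velocity)) == pytest.approx(35.0, abs=0.2)

    def test_constant_trace_zero_velocity(self):
        v = compute_velocity(_trace(np.full(100, 3.0)))
        np.testing.assert_allclose(v.velocity, 0.0, atol=1e-12)

    def test_window3_is_central_difference(self):
        rng = np.random.default_rng(0)
        trace = _trace(rng.normal(size=50))
        v3 = compute_velocity(trace, window_samples=3).velocity
        central = np.gradient(trace.angle) * 200.0
        np.testing.assert_allclose(v3[1:-1], central[1:-1], atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            compute_velocity(_trace(np.zeros(10)), window_samples=4)


@pytest.fixture
def scored_session(short_stim):
    sess = generate_session(short_stim, EyePlantParams(
        gain_up=0.8, gain_down=0.8, noise_sd=0.0))
    segs = segment_steps(sess.platform_trace)
    eye_vel = compute_velocity(sess.eye_trace)
    return sess, segs, eye_vel


class TestPeakResponse:
    def test_proportional_plant_closed_form(self, scored_session):
        _, segs, eye_vel = scored_session
        for seg in segs:
            if seg.phase == "toward":
                assert peak_response(eye_vel, seg) == pytest.approx(
                    0.8 * 35.0, rel=0.02)

    def test_zero_gain_plant(self, short_stim):
        sess = generate_session(short_stim,
                                EyePlantParams(gain_up=0.0, gain_down=0.0))
        segs = segment_steps(sess.platform_trace)
        eye_vel = compute_velocity(sess.eye_trace)
        assert peak_response(eye_vel, segs[0]) == 0.0

    def test_single_sample_window(self, scored_session):
        _, segs, eye_vel = scored_session
        seg = segs[0]
        fs = 200.0
        got = peak_response(eye_vel, seg, window=1.0 / fs)
        window_v = eye_vel.velocity[seg.onset_index:seg.onset_index + 2]
        assert got == pytest.approx(np.max(np.abs(window_v)), abs=1e-9)

    def test_window_past_trace_end_errors(self, scored_session):
        _, segs, eye_vel = scored_session
        with pytest.raises(ValueError, match="window extends"):
            peak_response(eye_vel, segs[-1], window=1e6)


class TestRejectArtifacts:
    def test_clean_session_keeps_everything(self, scored_session):
        sess, segs, eye_vel = scored_session
        out = reject_artifacts(sess.eye_trace, eye_vel, segs)
        assert all(r.retained for r in out)

    def test_injected_saccade_rejects_exactly_that_step(self, scored_session):
        sess, segs, eye_vel = scored_session
        eye = sess.eye_angle.copy()
        hit = segs[2].onset_index + 50  # inside step 2's response window
        eye[hit:] += 10.0               # single-sample 10 deg jump
        eye_trace = _trace(eye)
        eye_vel2 = compute_velocity(eye_trace)
        out = reject_artifacts(eye_trace, eye_vel2, segs)
        assert [r.retained for r in out] == \
            [i != 2 for i in range(len(segs))]
        assert out[2].rejection_reason == "saccade"

    def test_degenerate_ceiling_rejects_all(self, scored_session):
        sess, segs, eye_vel = scored_session
        out = reject_artifacts(sess.eye_trace, eye_vel, segs,
                               vel_ceiling=0.01)
        assert not any(r.retained for r in out)

    def test_empty_segments_empty_result(self, scored_session):
        sess, _, eye_vel = scored_session
        assert reject_artifacts(sess.eye_trace, eye_vel, []) == []


class TestFishGain:
    def test_direction_specific_recovery(self, short_stim):
        sess = generate_session(short_stim, EyePlantParams(
            gain_up=0.5, gain_down=0.9, noise_sd=0.0))
        fr, _ = fish_gain(sess.platform_trace, sess.eye_trace)
        assert fr.gain_up == pytest.approx(0.50, abs=0.01)
        assert fr.gain_down == pytest.approx(0.90, abs=0.01)
        assert fr.n_retained_up == short_stim.n_cycles
        assert fr.n_retained_down == short_stim.n_cycles

    def test_identity_plant_gain_one(self, short_stim):
        sess = generate_session(short_stim,
                                EyePlantParams(gain_up=1.0, gain_down=1.0))
        fr, _ = fish_gain(sess.platform_trace, sess.eye_trace)
        assert fr.gain_up == pytest.approx(1.0, abs=0.01)
        assert fr.gain_down == pytest.approx(1.0, abs=0.01)

    def test_all_rejected_reports_missing_not_zero(self, short_stim):
        sess = generate_session(short_stim,
                                EyePlantParams(gain_up=0.8, gain_down=0.8))
        cfg = GainConfig(vel_ceiling=0.01)
        fr, audit = fish_gain(sess.platform_trace, sess.eye_trace, config=cfg)
        assert fr.gain_up is None and fr.gain_down is None
        assert fr.missing_reason["nose_up"] == "no retained steps"
        assert all(not r.retained for r in audit)

    def test_offset_invariance(self, short_stim):
        sess = generate_session(short_stim, EyePlantParams(
            gain_up=0.6, gain_down=0.6))
        fr_a, _ = fish_gain(sess.platform_trace, sess.eye_trace)
        shifted = _trace(sess.eye_angle + 4.2)
        fr_b, _ = fish_gain(sess.platform_trace, shifted)
        assert fr_a.gain_up == pytest.approx(fr_b.gain_up, abs=1e-12)
        assert fr_a.gain_down == pytest.approx(fr_b.gain_down, abs=1e-12)

    def test_gain_monotone_in_injected_gain(self, short_stim):
        estimates = []
        for g in [0.1, 0.4, 0.7, 1.0, 1.2]:
            sess = generate_session(short_stim,
                                    EyePlantParams(gain_up=g, gain_down=g))
            fr, _ = fish_gain(sess.platform_trace, sess.eye_trace)
            estimates.append(fr.gain_up)
        assert np.all(np.diff(estimates) > 0)

    def test_rejection_does_not_change_retained_peaks(self, scored_session):
        """Exclusion and measurement are independent: retained steps keep
        identical peak values whatever the ceilings."""
        sess, segs, _ = scored_session
        _, audit_loose = fish_gain(sess.platform_trace, sess.eye_trace,
                                   segments=segs)
        cfg = GainConfig(jump_ceiling=0.05)
        _, audit_tight = fish_gain(sess.platform_trace, sess.eye_trace,
                                   segments=segs, config=cfg)
        for a, b in zip(audit_loose, audit_tight):
            if not (np.isnan(a.peak_eye_velocity)
                    or np.isnan(b.peak_eye_velocity)):
                assert a.peak_eye_velocity == b.peak_eye_velocity
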