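"""PFR measures: projection algebra, epoch extraction, round trips,
time-locked averages, endpoint shift and distractor projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfrkit import pfr, saccades
from pfrkit.gaze_synth import OculomotorProfile, make_trial, square_layout
from pfrkit.trace_io import GazeTrace

DT = 1000.0 / 220.0


def noiseless(**kw):
    base = dict(
        open_loop_gain=0.0,
        foveal_gain=0.0,
        landing_mae_deg=0.0,
        misselect_prob=0.0,
        fixation_noise_sd_deg=0.0,
    )
    base.update(kw)
    return OculomotorProfile(**base)


def detect_primary(rec):
    evs = saccades.detect(rec.trace)
    return saccades.primary_saccade(evs, rec.trace, rec.cue_time_ms)


class TestProject:
    def test_dot_product(self):
        assert pfr.project(np.array([3.0, 4.0]), np.array([0.6, 0.8])) == pytest.approx(5.0)

    def test_orthogonal_gives_zero(self):
        assert pfr.project(np.array([2.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_opposite_motion_negative(self):
        assert pfr.project(np.array([-1.0, 0.0]), np.array([1.0, 0.0])) == -1.0

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            pfr.project(np.array([1.0, 0.0]), np.array([1.0, 1.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        v1=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
        v2=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_linearity(self, v1, v2, a, b, angle):
        d = np.array([np.cos(angle), np.sin(angle)])
        v1, v2 = np.array(v1), np.array(v2)
        lhs = pfr.project(a * v1 + b * v2, d)
        rhs = a * pfr.project(v1, d) + b * pfr.project(v2, d)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestOpenLoopPfr:
    def test_noise_free_gain_round_trip(self):
        """Constructed drift at gain 0.1 recovers 0.100 up to sample quantization."""
        rec = make_trial(noiseless(open_loop_gain=0.1), square_layout(0, False), 17)
        m = pfr.open_loop_pfr(rec.trace, detect_primary(rec), rec.layout)
        # one sample of drift at 1 deg/s over the 80 ms epoch
        tol = 1.0 * (DT / 1000.0) / 0.080 / 10.0 + 2e-3
        assert m.valid
        assert m.gain == pytest.approx(0.1, abs=tol + 0.1 * DT / 80.0)

    def test_zero_drift_gain_zero(self):
        rec = make_trial(noiseless(), square_layout(1, False), 4)
        m = pfr.open_loop_pfr(rec.trace, detect_primary(rec), rec.layout)
        assert m.gain == pytest.approx(0.0, abs=1e-9)

    def test_gain_is_projection_over_speed(self):
        rec = make_trial(noiseless(open_loop_gain=0.12), square_layout(2, False), 6)
        m = pfr.open_loop_pfr(rec.trace, detect_primary(rec), rec.layout)
        assert m.gain == pytest.approx(m.projected_velocity / rec.layout.target_speed)

    def test_offset_invariance(self):
        """Adding a constant position offset leaves the measure unchanged."""
        rec = make_trial(OculomotorProfile(), square_layout(0, True), 23)
        ev = detect_primary(rec)
        m1 = pfr.open_loop_pfr(rec.trace, ev, rec.layout)
        shifted = GazeTrace(
            rec.trace.t_ms, rec.trace.x_deg + 3.7, rec.trace.y_deg - 1.2, rec.trace.valid
        )
        m2 = pfr.open_loop_pfr(shifted, ev, rec.layout)
        assert m2.gain == pytest.approx(m1.gain, abs=1e-12)

    def test_radial_residual_projects_to_zero(self):
        """Drift along the saccade (radial) axis contributes nothing: the
        motion direction is tangential, hence orthogonal."""
        t = np.arange(300) * DT
        center = np.array([5.0, 5.0])
        radial = center / np.linalg.norm(center)
        u = np.clip((t - 500.0) / 40.0, 0, 1)
        xy = center[None, :] * (0.5 * (1 - np.cos(np.pi * u)))[:, None]
        post = np.clip(t - 540.0, 0, None) / 1000.0  # radial drift 2 deg/s
        xy = xy + (radial * 2.0)[None, :] * post[:, None]
        tr = GazeTrace(t, xy[:, 0], xy[:, 1])
        lay = square_layout(0, False)
        ev = saccades.primary_saccade(saccades.detect(tr), tr, 200.0)
        m = pfr.open_loop_pfr(tr, ev, lay)
        assert m.projected_velocity == pytest.approx(0.0, abs=1e-9)

    def test_short_trace_flagged_invalid(self):
        rec = make_trial(noiseless(), square_layout(0, False), 8)
        ev = detect_primary(rec)
        n_keep = ev.offset_idx + 5  # ends well before +100 ms
        short = GazeTrace(
            rec.trace.t_ms[:n_keep], rec.trace.x_deg[:n_keep], rec.trace.y_deg[:n_keep]
        )
        m = pfr.open_loop_pfr(short, ev, rec.layout)
        assert not m.valid and np.isnan(m.gain)


class TestFovealGain:
    def test_noise_free_present_round_trip(self):
        rec = make_trial(
            noiseless(open_loop_gain=0.05, foveal_gain=0.15), square_layout(0, True), 19
        )
        m = pfr.foveal_gain(rec.trace, detect_primary(rec), rec.layout)
        assert m.epoch == "foveal"
        assert m.gain == pytest.approx(0.15, abs=0.012)

    def test_absent_decays_below_open_loop(self):
        """With no foveal motion, 100-200 ms drift is below the open-loop gain."""
        rec = make_trial(
            noiseless(open_loop_gain=0.2, foveal_gain=0.2), square_layout(0, False), 20
        )
        ev = detect_primary(rec)
        fov = pfr.foveal_gain(rec.trace, ev, rec.layout)
        ol = pfr.open_loop_pfr(rec.trace, ev, rec.layout)
        assert fov.gain < ol.gain

    def test_mixed_session_recovery(self, intact_cohort):
        """Cohort-level foveal gain on present trials recovers the generator value."""
        rec_mean = intact_cohort["foveal_gain"].mean()
        sem = intact_cohort["foveal_gain"].std(ddof=1) / np.sqrt(len(intact_cohort))
        assert abs(rec_mean - 0.186) < max(3 * sem, 0.01)


class TestTimelockAverage:
    def _trials(self, gains, seed=0, present=True):
        out, pids = [], []
        for pid, g in enumerate(gains):
            rec = make_trial(noiseless(open_loop_gain=g, foveal_gain=g),
                             square_layout(0, present), 100 + seed + pid)
            ev = detect_primary(rec)
            out.append((rec.trace, ev, rec.layout))
            pids.append(pid)
        return out, pids

    def test_identical_trials_zero_dispersion(self):
        trials, _ = self._trials([0.1])
        trials = trials * 3
        avg = pfr.timelock_average(trials, [0, 0, 0], align="offset", condition="present")
        assert np.allclose(avg.dispersion, 0.0)

    def test_two_participant_mean(self):
        """Participant means 1 and 3 deg/s average to 2 on the open-loop plateau."""
        trials, pids = self._trials([0.1, 0.3])
        avg = pfr.timelock_average(trials, pids, align="offset", condition="present")
        plateau = (avg.t_ms >= 40) & (avg.t_ms <= 90)
        assert np.mean(avg.mean[plateau]) == pytest.approx(2.0, rel=0.1)

    def test_open_loop_plateau_matches_gain(self):
        trials, pids = self._trials([0.15, 0.15, 0.15], seed=40)
        avg = pfr.timelock_average(trials, pids, align="offset", condition="present")
        plateau = (avg.t_ms >= 40) & (avg.t_ms <= 90)
        assert np.mean(avg.mean[plateau]) == pytest.approx(1.5, rel=0.1)

    def test_onset_alignment_window(self):
        trials, pids = self._trials([0.1])
        avg = pfr.timelock_average(trials, pids, align="onset", condition="present")
        assert avg.t_ms[0] >= -101 and avg.t_ms[-1] <= 1

    def test_empty_condition_raises(self):
        trials, pids = self._trials([0.1], present=True)
        with pytest.raises(ValueError):
            pfr.timelock_average(trials, pids, align="offset", condition="absent")


class TestEndpointShift:
    def test_zero_for_exact_landings(self):
        rec = make_trial(noiseless(), square_layout(0, False), 3)
        ev = detect_primary(rec)
        ev.offset_pos = rec.layout.target_center.copy()
        assert pfr.endpoint_shift([(ev, rec.layout)]) == pytest.approx(0.0)

    def test_constant_shift_recovered(self):
        rec = make_trial(noiseless(), square_layout(0, False), 3)
        ev = detect_primary(rec)
        lay = rec.layout
        ev.offset_pos = lay.target_center + 0.3 * lay.target_motion_dir
        assert pfr.endpoint_shift([(ev, lay)] * 5) == pytest.approx(0.3)

    def test_gaussian_scatter_recovery(self):
        """Mean shift of scattered endpoints recovers a constructed 0.25 deg
        displacement along motion within 3 SE at n=1000."""
        rng = np.random.default_rng(9)
        lay = square_layout(0, False)
        sigma = 1.0
        trials = []
        rec = make_trial(noiseless(), lay, 3)
        base_ev = detect_primary(rec)
        for _ in range(1000):
            ev = saccades.SaccadeEvent(
                base_ev.onset_idx, base_ev.offset_idx, base_ev.onset_pos,
                lay.target_center + 0.25 * lay.target_motion_dir + rng.normal(0, sigma, 2),
                base_ev.amplitude_deg, base_ev.peak_velocity_deg_s,
            )
            trials.append((ev, lay))
        se = sigma / np.sqrt(1000)
        assert abs(pfr.endpoint_shift(trials) - 0.25) < 3 * se

    def test_no_trials_raises(self):
        with pytest.raises(ValueError):
            pfr.endpoint_shift([])


class TestDistractorPfr:
    def test_orthogonal_distractors_get_zero(self):
        """Drift exactly along the target's motion: distractors whose motion is
        orthogonal to it project to zero."""
        rec = make_trial(noiseless(open_loop_gain=0.1), square_layout(0, False), 30)
        ev = detect_primary(rec)
        gains = pfr.distractor_pfr(rec.trace, ev, rec.layout)
        assert set(gains) == {1, 2, 3}
        tdir = rec.layout.target_motion_dir
        for i, g in gains.items():
            expected = 0.1 * float(np.dot(rec.layout.motion_dirs[i], tdir))
            assert g == pytest.approx(expected, abs=0.01)

    def test_constructed_mixture_weights_recovered(self):
        """Drift = 0.8*target + 0.2*distractor motion: projections match the
        closed-form dot products of that mixture."""
        lay = square_layout(0, False)
        rec = make_trial(noiseless(), lay, 31)
        ev = detect_primary(rec)
        mix = 0.8 * lay.motion_dirs[0] + 0.2 * lay.motion_dirs[1]
        t = rec.trace.t_ms
        t_off = t[ev.offset_idx]
        ramp = np.clip(t - t_off, 0, None) / 1000.0  # 1 deg/s mixture drift
        xy = rec.trace.xy + ramp[:, None] * mix[None, :]
        tr = GazeTrace(t, xy[:, 0], xy[:, 1])
        gains = pfr.distractor_pfr(tr, ev, lay)
        target_gain = pfr.open_loop_pfr(tr, ev, lay).gain
        for i in (1, 2, 3):
            expected = float(np.dot(mix, lay.motion_dirs[i])) / lay.target_speed
            # absolute values carry nearest-sample quantization (<3%); the
            # ratios to the target projection are exact linear algebra
            assert gains[i] == pytest.approx(expected, rel=0.03, abs=1e-9)
            expected_ratio = expected / (float(np.dot(mix, lay.motion_dirs[0])) / 10.0)
            assert gains[i] / target_gain == pytest.approx(expected_ratio, abs=1e-9)

    def test_null_session_all_zero(self):
        rec = make_trial(noiseless(), square_layout(0, False), 32)
        ev = detect_primary(rec)
        gains = pfr.distractor_pfr(rec.trace, ev, rec.layout)
        assert all(abs(g) < 1e-9 for g in gains.values())
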