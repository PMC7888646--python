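import numpy as np
import pytest
from scipy.stats import norm

from stepspace.sensor_io import MultiSensorRecording
from stepspace.steps import (
    EpochMatrix, FLAG_EDGE, FLAG_OK, FLAG_TOO_SHORT, StepEventSeries,
    detect_step_onsets, exclude_rotational_steps, extract_epochs,
    first_pc_scores, harmonize_axes, rotational_step_mask,
)

RATE = 128.0


def burst_trace(times_s, duration_s=5.0, amp=8.0, sigma=0.05, freq=5.0):
    """Tri-axial trace whose sagittal magnitude is a Gaussian envelope per burst.

    The anteroposterior/vertical pair is in quadrature, so the sagittal
    magnitude equals the envelope and the 2 m/s^2 upward crossing time is
    t0 - sigma * sqrt(2 ln(amp / 2)) in closed form.
    """
    n = int(duration_s * RATE)
    t = np.arange(n) / RATE
    sig = np.zeros((n, 3))
    for t0 in times_s:
        env = amp * np.exp(-((t - t0) ** 2) / (2 * sigma ** 2))
        phase = 2 * np.pi * freq * (t - t0)
        sig[:, 0] += env * np.sin(phase)
        sig[:, 2] += env * np.cos(phase)
    return sig


def crossing_time(t0, amp=8.0, sigma=0.05, threshold=2.0):
    return t0 - sigma * np.sqrt(2 * np.log(amp / threshold))


class TestDetectStepOnsets:
    def test_regular_bursts_all_ok(self):
        trace = burst_trace([1.3, 2.0, 2.7], duration_s=4.2)
        ev = detect_step_onsets(trace, RATE)
        assert ev.onsets.size == 3
        assert ev.flags == [FLAG_OK] * 3  # 0.7 s spacing > 0.625 s
        expected = [crossing_time(t) for t in (1.3, 2.0, 2.7)]
        np.testing.assert_allclose(ev.onset_times_s(), expected, atol=2 / RATE)

    def test_short_interval_flags_first_onset_too_short(self):
        trace = burst_trace([1.0, 1.4], duration_s=3.0)
        ev = detect_step_onsets(trace, RATE)
        assert ev.flags[0] == FLAG_TOO_SHORT  # 0.4 s <= 0.625 s
        assert ev.flags[1] == FLAG_OK

    def test_all_zero_trace_gives_no_onsets(self):
        ev = detect_step_onsets(np.zeros((512, 3)), RATE)
        assert ev.onsets.size == 0

    def test_onset_too_close_to_start_flagged_edge(self):
        trace = burst_trace([0.15, 1.2], duration_s=3.0)
        ev = detect_step_onsets(trace, RATE)
        assert ev.flags[0] == FLAG_EDGE
        assert ev.flags[1] == FLAG_OK

    def test_refractory_suppresses_secondary_crossings_within_burst(self):
        # a non-quadrature burst whose magnitude oscillates through threshold
        n = int(3.0 * RATE)
        t = np.arange(n) / RATE
        sig = np.zeros((n, 3))
        env = 8.0 * np.exp(-((t - 1.5) ** 2) / (2 * 0.05 ** 2))
        sig[:, 0] = env * np.sin(2 * np.pi * 5 * (t - 1.5))
        ev = detect_step_onsets(sig, RATE)
        assert ev.onsets.size == 1

    def test_translation_equivariance(self):
        times = [1.3, 2.0, 2.7]
        k = 13
        a = burst_trace(times, duration_s=4.5)
        b = burst_trace([x + k / RATE for x in times], duration_s=4.5)
        ev_a = detect_step_onsets(a, RATE)
        ev_b = detect_step_onsets(b, RATE)
        np.testing.assert_array_equal(ev_b.onsets, ev_a.onsets + k)

    def test_strictly_increasing_onsets_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StepEventSeries("left", [10, 10], [FLAG_OK, FLAG_OK], RATE)


class TestExtractEpochs:
    def _recording(self, data):
        return MultiSensorRecording("p", "s", RATE, {"lumbar": data})

    def test_window_samples_and_row_length(self):
        data = np.arange(1500 * 3, dtype=float).reshape(1500, 3)
        rec = self._recording(data)
        ev = StepEventSeries("left", [1000], [FLAG_OK], RATE)
        em = extract_epochs(rec, ev, "lumbar")
        assert em.rows.shape == (1, 480)  # 160 samples x 3 axes
        # x-block is samples [968, 1128) of column 0
        np.testing.assert_array_equal(em.rows[0, :160], data[968:1128, 0])
        np.testing.assert_array_equal(em.rows[0, 160:320], data[968:1128, 1])

    def test_non_ok_steps_skipped(self):
        rec = self._recording(np.zeros((1000, 3)))
        ev = StepEventSeries("left", [10, 500], [FLAG_EDGE, FLAG_OK], RATE)
        em = extract_epochs(rec, ev, "lumbar")
        assert em.n_steps == 1
        assert em.step_ids.tolist() == [500]

    def test_zero_recording_gives_zero_rows(self):
        rec = self._recording(np.zeros((2000, 3)))
        onsets = [200, 400, 600, 800, 1000]
        ev = StepEventSeries("left", onsets, [FLAG_OK] * 5, RATE)
        em = extract_epochs(rec, ev, "lumbar")
        assert em.n_steps == 5
        assert np.all(em.rows == 0)

    def test_velocity_kind_integrates_each_epoch(self):
        data = np.ones((1000, 3))
        rec = self._recording(data)
        ev = StepEventSeries("left", [500], [FLAG_OK], RATE)
        em = extract_epochs(rec, ev, "lumbar", signal_kind="velocity")
        # constant 1 m/s^2 over 160 samples: trapezoid ends at 159/128
        assert em.rows[0, 0] == 0.0
        assert em.rows[0, 159] == pytest.approx(159.0 / 128.0)


class TestRotationalExclusion:
    def test_identical_steps_all_retained(self):
        rows = np.tile(np.linspace(0, 1, 40), (20, 1))
        keep = rotational_step_mask(rows)
        assert keep.all()

    def test_single_low_outlier_removed(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=30)
        u /= np.linalg.norm(u)
        if u[np.argmax(np.abs(u))] < 0:  # match the PC sign convention
            u = -u
        scores = np.concatenate([rng.normal(0, 1, 19), [-8.0]])
        rows = np.outer(scores, u) + rng.normal(0, 0.01, (20, 30))
        em = EpochMatrix("lumbar", "left", "acceleration", rows,
                         np.arange(20))
        kept = exclude_rotational_steps(em)
        removed = set(range(20)) - set(kept.step_ids.tolist())
        assert removed == {19}

    def test_normal_scores_removal_fraction_matches_gaussian_tail(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=10000)
        u = np.array([1.0, 0.0, 0.0])
        rows = np.outer(scores, u)
        keep = rotational_step_mask(rows, n_sd=1.0)
        frac_removed = 1.0 - keep.mean()
        assert frac_removed == pytest.approx(norm.cdf(-1.0), abs=0.01)

    def test_literal_direction_removes_majority(self):
        rng = np.random.default_rng(2)
        rows = np.outer(rng.normal(size=1000), np.ones(4))
        keep = rotational_step_mask(rows, direction="above")
        assert keep.mean() < 0.5

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rotational_step_mask(np.zeros((2, 10)))


class TestHarmonizeAxes:
    def _epochs(self, sensor):
        rng = np.random.default_rng(8)
        return EpochMatrix(sensor, "left", "acceleration",
                           rng.normal(size=(4, 30)), np.arange(4))

    def test_left_sensor_ml_block_negated(self):
        em = self._epochs("left_wrist")
        out = harmonize_axes(em)
        L = em.epoch_len
        np.testing.assert_array_equal(out.rows[:, L:2 * L], -em.rows[:, L:2 * L])
        np.testing.assert_array_equal(out.rows[:, :L], em.rows[:, :L])
        np.testing.assert_array_equal(out.rows[:, 2 * L:], em.rows[:, 2 * L:])

    def test_right_sensor_unchanged(self):
        em = self._epochs("right_foot")
        np.testing.assert_array_equal(harmonize_axes(em).rows, em.rows)

    def test_involution_on_left_sensor(self):
        em = self._epochs("left_foot")
        twice = harmonize_axes(harmonize_axes(em))
        np.testing.assert_array_equal(twice.rows, em.rows)

    def test_explicit_side_overrides_sensor_side(self):
        em = self._epochs("lumbar")
        out = harmonize_axes(em, side_of_sensor="left")
        L = em.epoch_len
        np.testing.assert_array_equal(out.rows[:, L:2 * L], -em.rows[:, L:2 * L])
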