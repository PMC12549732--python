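import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_child
from gaittwin.errors import (EventSequenceError, InsufficientStrides,
                             NoStridesDetected, ValidationError)
from gaittwin.events import (EventConfig, StrideSeries, detect_gait_events,
                             poincare, symmetry_index, symmetry_indices,
                             temporal_parameters)
from gaittwin.gaitsim import GaitParams, generate_gait_trial


def _match_errors(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-event distance (s) to the nearest ground-truth event."""
    return np.array([np.min(np.abs(truth - t)) for t in detected])


class TestDetection:
    def test_noise_free_round_trip_within_one_sample(self, clean_trial):
        trial, _, params = clean_trial
        s = detect_gait_events(trial.shank_gyro_left, trial.fs, leg="left")
        assert len(s.mid_swings) == len(trial.truth.mid_swings_left)
        for det, tru in ((s.mid_swings, trial.truth.mid_swings_left),
                         (s.heel_strikes, trial.truth.heel_strikes_left),
                         (s.toe_offs, trial.truth.toe_offs_left)):
            assert _match_errors(det, tru).max() <= 1.0 / trial.fs + 1e-9

    def test_noisy_detection_within_three_samples(self):
        """Monte Carlo: 10 deg/s broadband gyro noise, 20 seeds."""
        child = make_child()
        params = GaitParams(duration_s=21.0, stride_time_mean=1.0,
                            stride_time_sd=0.0, gyro_noise_sd=10.0)
        worst = []
        for seed in range(20):
            trial = generate_gait_trial(child, params, seed=seed)
            s = detect_gait_events(trial.shank_gyro_left, trial.fs)
            errs = np.concatenate([
                _match_errors(s.mid_swings, trial.truth.mid_swings_left),
                _match_errors(s.heel_strikes, trial.truth.heel_strikes_left),
                _match_errors(s.toe_offs, trial.truth.toe_offs_left)])
            worst.append(errs.max())
        assert np.median(worst) <= 3.0 / params.fs + 1e-9
        assert np.max(worst) <= 5.0 / params.fs + 1e-9

    def test_all_zero_signal_raises(self):
        with pytest.raises(NoStridesDetected):
            detect_gait_events(np.zeros(1000), fs=100.0)

    def test_too_few_strides_raises(self):
        fs = 100.0
        t = np.arange(int(3 * fs)) / fs
        x = 200 * np.exp(-0.5 * ((t - 1.5) / 0.05) ** 2)   # single swing peak
        with pytest.raises(InsufficientStrides):
            detect_gait_events(x, fs)

    def test_auto_axis_selection_picks_sagittal(self, clean_trial):
        trial, _, _ = clean_trial
        from_block = detect_gait_events(trial.shank_gyro_left, trial.fs)
        from_axis = detect_gait_events(trial.shank_gyro_left[:, 2], trial.fs)
        assert np.array_equal(from_block.mid_swings, from_axis.mid_swings)


def _hand_events(n=6, offset=0.0):
    """The worked event pattern: strideT=1, stepT=0.5, stance 62%, DS 24%."""
    k = np.arange(n, dtype=float)
    left = StrideSeries("left", heel_strikes=k + offset,
                        toe_offs=k + 0.62 + offset,
                        mid_swings=k + 0.8 + offset)
    right = StrideSeries("right", heel_strikes=k + 0.5 + offset,
                         toe_offs=k + 1.12 + offset,
                         mid_swings=k + 1.3 + offset)
    return left, right


class TestTemporalParams:
    def test_hand_computed_example(self):
        left, right = _hand_events()
        tp = temporal_parameters(left, right, body_length_m=0.80)
        assert tp.strideT == pytest.approx(1.0, abs=1e-9)
        assert tp.stepT == pytest.approx(0.5, abs=1e-9)
        assert tp.stanceT == pytest.approx(62.0, abs=1e-6)
        assert tp.DS == pytest.approx(24.0, abs=1e-6)
        assert tp.nstrideT == pytest.approx(1.0 / np.sqrt(0.80 / 9.81), abs=1e-9)
        assert round(tp.nstrideT, 2) == 3.50

    def test_time_offset_invariance(self):
        tp0 = temporal_parameters(*_hand_events(offset=0.0))
        tp9 = temporal_parameters(*_hand_events(offset=97.3))
        for attr in ("strideT", "stepT", "stanceT", "DS"):
            assert getattr(tp0, attr) == pytest.approx(getattr(tp9, attr), abs=1e-9)

    def test_periodic_trial_constant_stride_list(self, clean_trial):
        trial, _, _ = clean_trial
        left = detect_gait_events(trial.shank_gyro_left, trial.fs, leg="left")
        right = detect_gait_events(trial.shank_gyro_right, trial.fs, leg="right")
        tp = temporal_parameters(left, right)
        assert np.ptp(tp.stride_times_left) <= 2.0 / trial.fs

    def test_stride_equals_sum_of_steps(self, clean_trial):
        trial, _, _ = clean_trial
        left = detect_gait_events(trial.shank_gyro_left, trial.fs, leg="left")
        right = detect_gait_events(trial.shank_gyro_right, trial.fs, leg="right")
        tp = temporal_parameters(left, right)
        assert tp.strideT == pytest.approx(
            np.mean(tp.step_times_left) + np.mean(tp.step_times_right),
            abs=1.0 / trial.fs)

    def test_non_interleaved_events_raise(self):
        left, right = _hand_events()
        bad_right = StrideSeries("right", heel_strikes=right.heel_strikes + 2.0,
                                 toe_offs=right.toe_offs + 2.0,
                                 mid_swings=right.mid_swings + 2.0)
        with pytest.raises(EventSequenceError):
            temporal_parameters(left, bad_right)

    def test_missing_body_length_warns_and_skips_normalization(self):
        with pytest.warns(UserWarning):
            tp = temporal_parameters(*_hand_events())
        assert tp.nstrideT is None


class TestSymmetry:
    def test_closed_forms(self):
        assert symmetry_index(1.0, 1.0) == 0.0
        assert symmetry_index(1.1, 0.9) == pytest.approx(20.0, abs=1e-9)
        assert symmetry_index(0.9, 1.1) == pytest.approx(20.0, abs=1e-9)

    def test_leg_relabelling_invariance(self):
        left, right = _hand_events()
        tp = temporal_parameters(left, right)
        swapped = temporal_parameters(
            StrideSeries("left", right.heel_strikes, right.toe_offs, right.mid_swings),
            StrideSeries("right", left.heel_strikes + 1.0, left.toe_offs + 1.0,
                         left.mid_swings + 1.0))
        assert symmetry_indices(tp)[0] == pytest.approx(
            symmetry_indices(swapped)[0], abs=1e-9)


class TestPoincare:
    def test_constant_series(self):
        r = poincare([1.0] * 10)
        assert (r.SD1, r.SD2, r.std) == (0.0, 0.0, 0.0)

    def test_alternating_series_closed_form(self):
        x = [0.9, 1.1] * 10
        r = poincare(x)
        assert r.SD1 == pytest.approx(0.2 / np.sqrt(2), abs=1e-12)
        assert r.SD2 == pytest.approx(0.0, abs=1e-9)
        assert r.std == pytest.approx(0.1, abs=1e-12)

    def test_iid_gaussian_sd1_equals_sd2(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10_000)
        r = poincare(x)
        assert r.SD1 == pytest.approx(1.0, rel=0.05)
        assert r.SD2 == pytest.approx(1.0, rel=0.05)

    def test_short_series_raises(self):
        with pytest.raises(ValidationError):
            poincare([1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=60))
    def test_pythagoras_identity(self, xs):
        r = poincare(xs)
        lhs = r.SD1 ** 2 + r.SD2 ** 2
        rhs = 2 * r.std ** 2
        scale = max(1.0, rhs)
        # exact identity unless SD2 was floored at zero (documented clip)
        assert lhs == pytest.approx(rhs, abs=1e-9 * scale) or (
            r.SD2 == 0.0 and lhs >= rhs - 1e-9 * scale)
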