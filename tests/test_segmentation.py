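import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spastiq.exceptions import OnsetNotFoundError
from spastiq.kinematics import AngleTrajectory
from spastiq.segmentation import (
    SegmentationConfig,
    StretchSegment,
    detect_angle_onset,
    detect_semg_onset,
    find_max_angle,
    segment_trial,
    windows,
)
from spastiq.io import TrialRecording

FS = 2000.0


def _traj(theta, omega):
    return AngleTrajectory(theta=np.asarray(theta, float),
                           omega_res=np.asarray(omega, float), fs=FS)


class TestAngleOnset:
    def test_matches_brute_force_scan(self):
        n = 5000
        omega = np.linspace(0, 20, n)
        theta = np.linspace(0, 140, n)
        expected = next(
            i for i in range(n) if omega[i] > 7.1 and theta[i] > 1.2
        )
        assert detect_angle_onset(_traj(theta, omega)) == expected

    def test_thresholds_are_strict(self):
        theta = np.linspace(0, 140, 1000)
        omega = np.full(1000, 7.0)
        with pytest.raises(OnsetNotFoundError):
            detect_angle_onset(_traj(theta, omega))

    def test_later_crossing_wins_when_staggered(self):
        n = 1000
        theta = np.linspace(0, 50, n)          # crosses 1.2 deg early
        omega = np.zeros(n)
        omega[600:] = 10.0                      # velocity crosses later
        assert detect_angle_onset(_traj(theta, omega)) == 600


class TestMaxAngle:
    def test_unimodal_peak(self):
        theta = -np.abs(np.arange(5000) - 3000).astype(float)
        assert find_max_angle(_traj(theta, np.zeros_like(theta))) == 3000

    def test_plateau_breaks_tie_to_earliest(self):
        theta = np.zeros(4000)
        theta[3000:3101] = 5.0
        assert find_max_angle(_traj(theta, theta)) == 3000

    def test_monotone_series_peaks_at_end(self):
        theta = np.arange(100, dtype=float)
        assert find_max_angle(_traj(theta, theta)) == 99


class TestSemgOnset:
    def _noise(self, n, rng):
        return rng.normal(0.0, 1.0, size=n)

    def test_planted_burst_detected_near_truth(self, rng):
        n = 6000
        x = self._noise(n, rng)
        x[2000:3500] += 10.0 * rng.normal(size=1500)
        onset = detect_semg_onset(x, FS)
        assert onset is not None
        assert 2000 - 0.05 * FS <= onset <= 2000 + 0.05 * FS

    def test_pure_noise_yields_no_onset(self, rng):
        assert detect_semg_onset(self._noise(8000, rng), FS) is None

    def test_burst_inside_baseline_window_defeats_detection(self, rng):
        # documented limitation: the first baseline_ms must be quiet
        n = 6000
        x = self._noise(n, rng)
        x[:1000] += 10.0 * rng.normal(size=1000)
        assert detect_semg_onset(x, FS) is None


class TestSegmentTrial:
    def _trial(self, semg, group):
        n = semg.shape[0]
        return TrialRecording("s", "t", semg, np.zeros((n, 3)), fs=FS,
                              velocity_class="fast", mas_label=None, group=group)

    def _rising_traj(self, n):
        theta = np.linspace(0, 140, n)
        omega = np.full(n, 50.0)
        return _traj(theta, omega)

    def test_healthy_uses_angle_onset(self, rng):
        n = 6000
        semg = rng.normal(size=(n, 4))
        seg = segment_trial(self._trial(semg, "healthy"), self._rising_traj(n))
        assert seg.source == "angle_onset"
        assert seg.start_index < seg.end_index

    def test_patient_burst_uses_semg_onset(self, rng):
        n = 6000
        semg = rng.normal(size=(n, 4))
        semg[2500:5000, 0] += 10.0 * rng.normal(size=2500)
        traj = self._rising_traj(n)
        seg = segment_trial(self._trial(semg, "patient"), traj)
        assert seg.source == "semg_onset"
        assert seg.start_index < seg.end_index == find_max_angle(traj)

    def test_patient_without_burst_falls_back_with_warning(self, rng):
        n = 6000
        semg = rng.normal(size=(n, 4))
        with pytest.warns(UserWarning, match="no sEMG onset"):
            seg = segment_trial(self._trial(semg, "patient"), self._rising_traj(n))
        assert seg.source == "angle_onset"


class TestWindows:
    def _seg(self, length):
        return StretchSegment(0, length, 0.0, "angle_onset")

    @pytest.mark.parametrize("length,expected", [(256, 1), (512, 3), (255, 0), (640, 4)])
    def test_window_counts(self, length, expected):
        semg = np.zeros((length, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = windows(self._seg(length), semg)
        assert len(out) == expected
        if expected:
            offsets = [0, 128, 256][: min(expected, 3)]
            assert all(out[i].window_index == i for i in range(expected))
            assert all(w.samples.shape == (256, 4) for w in out)

    def test_short_segment_warns(self):
        with pytest.warns(UserWarning, match="shorter than one window"):
            assert windows(self._seg(100), np.zeros((100, 4))) == []

    @given(st.integers(min_value=256, max_value=5000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_count_formula_matches_enumeration(self, length):
        brute = sum(
            1 for start in range(0, length, 128) if start + 256 <= length
        )
        out = windows(self._seg(length), np.zeros((length, 4)))
        assert len(out) == brute == (length - 256) // 128 + 1
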