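"""Trial-locked extraction: overlap binning, pseudo-events, centering, windows."""

import numpy as np
import pytest

from sstlearn import (HrfSpec, RoiTimeSeries, RunConfig, center_timecourses,
                      condition_average, condition_contrast,
                      default_bin_centers, extract_trial_timecourse,
                      go_pseudo_event, hrf_kernel, synthesize_bold,
                      window_stat)
from sstlearn.bold_sim import RoiSignalSpec
from sstlearn.task_sim import (BehavioralRun, CORRECT_STOP, GO, STOP,
                               TrialRecord)
from sstlearn.timecourse import TrialTimecourse


def brute_force_extract(series, event_time, bin_centers, bin_width=0.1):
    """Oracle: for each bin scan every volume and test interval intersection."""
    out = np.full(len(bin_centers), np.nan)
    n = len(series.values)
    for j, c in enumerate(bin_centers):
        a = event_time + c - bin_width / 2 - series.t0
        b = a + bin_width
        hits = [series.values[i] for i in range(n)
                if i * series.tr < b and (i + 1) * series.tr > a]
        if hits:
            out[j] = np.mean(hits)
    return out


class TestExtraction:
    def test_constant_series_fills_every_bin(self):
        series = RoiTimeSeries("r", tr=2.0, values=np.full(200, 7.0))
        tc = extract_trial_timecourse(series, event_time=150.0)
        assert len(tc.values) == 301
        np.testing.assert_allclose(tc.values, 7.0)

    def test_bin_inside_single_volume(self):
        series = RoiTimeSeries("r", tr=2.0, values=np.arange(100, dtype=float))
        # event at 50.0; bin center +1.0 covers [50.95, 51.05) -> volume 25
        tc = extract_trial_timecourse(series, 50.0)
        j = np.argmin(np.abs(tc.bin_centers - 1.0))
        assert tc.values[j] == 25.0

    def test_bin_straddling_volume_boundary(self):
        # two volumes, values 1 and 3; bin centered on the boundary sees both
        series = RoiTimeSeries("r", tr=2.0, values=np.array([1.0, 3.0]))
        tc = extract_trial_timecourse(series, event_time=2.0,
                                      bin_centers=np.array([0.0]))
        oracle = brute_force_extract(series, 2.0, np.array([0.0]))
        assert tc.values[0] == pytest.approx(2.0)
        assert tc.values[0] == pytest.approx(oracle[0])

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        centers = default_bin_centers()
        for _ in range(40):
            n = rng.integers(5, 40)
            series = RoiTimeSeries("r", tr=2.0, values=rng.normal(size=n))
            event = float(rng.uniform(-5, n * 2 + 5))
            fast = extract_trial_timecourse(series, event).values
            slow = brute_force_extract(series, event, centers)
            np.testing.assert_allclose(fast, slow, atol=1e-12, equal_nan=True)

    def test_event_outside_series_warns_all_absent(self):
        series = RoiTimeSeries("r", tr=2.0, values=np.ones(5))
        with pytest.warns(UserWarning):
            tc = extract_trial_timecourse(series, event_time=500.0)
        assert np.all(np.isnan(tc.values))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=60)
        series = RoiTimeSeries("r", tr=2.0, values=values)
        base = extract_trial_timecourse(series, 40.0).values
        for k in (1, 3, 7):  # shift series and event by the same multiple of TR
            shifted = RoiTimeSeries("r", tr=2.0,
                                    values=np.r_[np.zeros(k), values])
            moved = extract_trial_timecourse(shifted, 40.0 + 2.0 * k).values
            np.testing.assert_allclose(base, moved, atol=1e-12, equal_nan=True)

    def test_binning_grid_contract(self):
        centers = default_bin_centers()
        assert len(centers) == 301
        assert centers[0] == -10.0 and centers[-1] == 20.0
        np.testing.assert_allclose(np.diff(centers), 0.1, atol=1e-9)


class TestPseudoEvent:
    def _run(self):
        cfg = RunConfig(ssd_init=0.25)
        return BehavioralRun("s", 1, cfg, [
            TrialRecord(1, GO, 0.0, rt=0.4),
            TrialRecord(2, STOP, 5.0, ssd=0.300, outcome=CORRECT_STOP),
            TrialRecord(3, GO, 10.0, rt=0.4),
            TrialRecord(4, GO, 15.0, rt=0.4),
        ])

    def test_uses_last_stop_ssd(self):
        run = self._run()
        assert go_pseudo_event(run, 3) == pytest.approx(10.0 + 0.300)
        # the same SSD applies to every subsequent go trial
        assert go_pseudo_event(run, 4) == pytest.approx(15.0 + 0.300)

    def test_falls_back_to_initial_ssd(self):
        run = self._run()
        assert go_pseudo_event(run, 1) == pytest.approx(0.0 + 0.25)

    def test_stop_trial_rejected(self):
        with pytest.raises(ValueError):
            go_pseudo_event(self._run(), 2)


def _course(values, condition="correct_stop", trial=1):
    values = np.asarray(values, dtype=float)
    return TrialTimecourse("s", 1, trial, condition,
                           bin_centers=np.arange(len(values), dtype=float),
                           values=values)


class TestCenteringAndAverages:
    def test_single_course_centers_to_zero(self):
        out = center_timecourses([_course([1.0, 2.0, 3.0])])
        np.testing.assert_allclose(out[0].values, 0.0)

    def test_two_courses_split_symmetrically(self):
        a, b = np.array([1.0, 4.0]), np.array([3.0, 0.0])
        out = center_timecourses([_course(a), _course(b)])
        np.testing.assert_allclose(out[0].values, (a - b) / 2)
        np.testing.assert_allclose(out[1].values, (b - a) / 2)

    def test_per_bin_mean_is_conserved_at_zero(self):
        rng = np.random.default_rng(0)
        courses = [_course(rng.normal(size=20), trial=i) for i in range(7)]
        out = center_timecourses(courses)
        stack = np.vstack([c.values for c in out])
        np.testing.assert_allclose(stack.mean(axis=0), 0.0, atol=1e-12)

    def test_identical_conditions_zero_contrast(self):
        courses = [_course([1.0, 2.0], "correct_stop"),
                   _course([1.0, 2.0], "failed_stop")]
        contrast = condition_contrast(condition_average(courses))
        np.testing.assert_allclose(contrast.mean, 0.0)

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(1)
        courses = ([_course(rng.normal(size=10), "correct_stop", i) for i in range(4)]
                   + [_course(rng.normal(size=10), "failed_stop", i) for i in range(4)])
        curves = condition_average(courses)
        fwd = condition_contrast(curves, "correct_stop", "failed_stop")
        rev = condition_contrast(curves, "failed_stop", "correct_stop")
        np.testing.assert_allclose(fwd.mean, -rev.mean)

    def test_missing_condition_warns(self):
        with pytest.warns(UserWarning):
            out = condition_contrast(condition_average([_course([1.0])]))
        assert np.all(np.isnan(out.mean))


class TestWindowStat:
    def _hrf_course(self):
        centers = default_bin_centers()
        kernel = hrf_kernel(HrfSpec.canonical(), 0.1)
        values = np.zeros(len(centers))
        start = np.argmin(np.abs(centers))  # event at bin center 0
        values[start:start + len(kernel)] = kernel[: len(centers) - start]
        return _course_with_centers(centers, values)

    def test_constant_window(self):
        course = _course([5.0] * 20)
        for stat in ("median", "peak", "trough"):
            assert window_stat(course, (4, 10), stat) == 5.0

    def test_linear_ramp_median_is_midpoint(self):
        centers = default_bin_centers()
        values = np.where((centers >= 4) & (centers <= 10), centers, 0.0)
        course = _course_with_centers(centers, values)
        # 61 bins from 4.0 to 10.0: sample median is the middle bin, 7.0
        assert window_stat(course, (4, 10), "median") == pytest.approx(7.0)

    def test_peak_median_trough_ordering(self):
        rng = np.random.default_rng(2)
        course = _course(rng.normal(size=30))
        w = (4, 10)
        assert (window_stat(course, w, "peak")
                >= window_stat(course, w, "median")
                >= window_stat(course, w, "trough"))

    def test_peak_of_embedded_hrf_matches_kernel_max(self):
        course = self._hrf_course()
        # unit-peak kernel: the windowed peak recovers the kernel max
        assert window_stat(course, (4, 10), "peak") == pytest.approx(1.0, abs=0.01)

    def test_all_absent_window_is_nan(self):
        centers = default_bin_centers()
        values = np.full(len(centers), np.nan)
        course = _course_with_centers(centers, values)
        assert np.isnan(window_stat(course, (4, 10), "median"))


def _course_with_centers(centers, values, condition="correct_stop"):
    return TrialTimecourse("s", 1, 1, condition, bin_centers=centers,
                           values=np.asarray(values, dtype=float))


def test_single_noise_free_event_recovered_within_binning_tolerance(
        one_run, one_run_signals):
    """End-to-end: an embedded unit event is recovered by extraction."""
    spec = RoiSignalSpec(roi="accumbens", salience_gain=0.0,
                         salience_pstop_gain=0.0, rpe_gain=0.0,
                         noise_sd=0.0, drift_amp=0.0)
    stop_time = next(t.stop_signal_time for t in one_run.trials
                     if t.trial_type == STOP)
    events = {"salience": (np.array([]), np.array([])),
              "rpe": (np.array([stop_time]), np.array([1.0]))}
    ts = synthesize_bold(one_run, one_run_signals, spec, seed=0, events=events)
    tc = extract_trial_timecourse(ts, stop_time)
    kernel = hrf_kernel(HrfSpec.canonical(), 0.1)
    post = tc.bin_centers >= 0
    expected = np.zeros(post.sum())
    expected[: len(kernel)] = kernel[: post.sum()]
    # the 2 s TR holds each sample constant, so pointwise error is bounded by
    # TR times the kernel's maximal slope
    staircase_bound = ts.tr * np.max(np.abs(np.diff(kernel))) / 0.1
    err = np.nanmax(np.abs(tc.values[post] - expected))
    assert err <= staircase_bound + 1e-6
    # shape recovery: unit peak at the canonical latency, high curve agreement
    assert np.nanmax(tc.values[post]) == pytest.approx(1.0, abs=0.25)
    peak_t = tc.bin_centers[post][np.nanargmax(tc.values[post])]
    assert 3.0 <= peak_t <= 8.0
    finite = np.isfinite(tc.values[post])
    r = np.corrcoef(tc.values[post][finite], expected[finite])[0, 1]
    assert r > 0.9
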