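import dataclasses as dc

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgchrono import (
    BurstWindow,
    DetectionConfig,
    detect_epoch,
    detect_onset,
    detect_partial,
    detect_windows,
    integrated_profile,
    merge_windows,
    render_epoch,
    validate_epoch,
)
from emgchrono.detection import (
    REJECT_NO_WINDOW,
    REJECT_NOT_LAST_WINDOW,
)
from emgchrono.preprocessing import BaselineStats
from conftest import make_epoch, step_epoch
from test_synthetic import zero_sd_params


class TestIntegratedProfile:
    def test_worked_example(self):
        np.testing.assert_array_equal(
            integrated_profile([0, 0, 1, 1]), [0, 0, 1, 2]
        )

    def test_all_zero(self):
        assert integrated_profile(np.zeros(5)).sum() == 0

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=50))
    def test_matches_explicit_loop(self, xs):
        ip = integrated_profile(xs)
        total = 0.0
        for x, v in zip(xs, ip):
            total += x
            assert v == pytest.approx(total)

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            integrated_profile([1.0, -0.5])


class TestDetectOnset:
    def test_worked_step_example(self):
        """Ten-sample window [0,0,0,0,0,0,1,1,1,1]: the deviation minimum
        falls at index 5, the onset at index 6."""
        x = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1], float)
        ep = make_epoch(x, t0_ms=0.0, press_time_ms=9.0)
        assert detect_onset(ep) == pytest.approx(6.0)

    def test_all_zero_window_gives_none(self):
        ep = make_epoch(np.zeros(2601), press_time_ms=800.0)
        assert detect_onset(ep) is None

    def test_no_press_gives_none(self):
        ep = step_epoch(500, 700)
        ep.press_time_ms = None
        assert detect_onset(ep) is None

    def test_step_recovered_exactly(self):
        for onset, press in [(300, 450), (518, 652), (900, 1100)]:
            assert detect_onset(step_epoch(onset, press)) == pytest.approx(onset)

    def test_search_excludes_post_press_signal(self):
        ep = step_epoch(600, 740)
        noisy = ep.samples.copy()
        noisy[0, ep.index_of(800):] = 50.0  # post-press artifact
        ep2 = make_epoch(noisy[0], press_time_ms=740.0)
        assert detect_onset(ep2) == detect_onset(ep)

    @settings(derandomize=True, max_examples=20)
    @given(amplitude=st.floats(0.01, 100.0), seed=st.integers(0, 10_000))
    def test_noise_free_exactness_any_amplitude(self, amplitude, seed, trials_one):
        """On noise-free rendered bursts the detected onset equals the true
        burst onset within one sample, for any burst amplitude > 0."""
        p = zero_sd_params(baseline_noise_sd=0.0, burst_amplitude=5.0)
        trial = trials_one[~trials_one.timeout].iloc[seed % 100]
        ep = render_epoch(trial, p, rng=seed)
        ep.samples *= amplitude  # detection must be scale-free
        onset = detect_onset(ep)
        assert abs(onset - ep.meta["true_onset_ms"]) <= 1.0

    def test_error_decreases_with_snr(self, trials_one):
        medians = []
        sub = trials_one[~trials_one.timeout].head(150)
        for ratio in (2.0, 5.0, 10.0):
            p = zero_sd_params(baseline_noise_sd=1.0, burst_amplitude=ratio)
            errs = []
            for k, (_, trial) in enumerate(sub.iterrows()):
                ep = render_epoch(trial, p, rng=1000 + k)
                errs.append(abs(detect_onset(ep) - ep.meta["true_onset_ms"]))
            medians.append(np.median(errs))
        assert medians[0] >= medians[1] >= medians[2]
        assert medians[1] <= 10.0


UNIT_STATS = BaselineStats(0.0, 1.0 / 3.5)  # threshold exactly 1.0


def window_epoch(spans, press_time_ms=None, value=2.0, n=2601):
    x = np.zeros(n)
    ep = make_epoch(x, press_time_ms=press_time_ms)
    for start, end in spans:
        x[ep.index_of(start):ep.index_of(end)] = value
    ep.samples[0] = x
    return ep


class TestDetectWindows:
    def test_sub_gap_runs_merge(self):
        ep = window_epoch([(600, 680), (700, 760)])
        (w,) = detect_windows(ep, stats=UNIT_STATS)
        assert (w.start_ms, w.end_ms) == (600.0, 760.0)

    def test_short_window_dropped(self):
        ep = window_epoch([(900, 940)])
        assert detect_windows(ep, stats=UNIT_STATS) == []

    def test_window_starting_after_press_dropped(self):
        ep = window_epoch([(850, 950)], press_time_ms=800.0)
        assert detect_windows(ep, stats=UNIT_STATS) == []
        ep2 = window_epoch([(850, 950)])  # no press rule on request
        assert len(detect_windows(ep2, stats=UNIT_STATS)) == 1

    def test_gap_at_threshold_not_merged(self):
        ep = window_epoch([(600, 680), (705, 760)])  # exactly 25 ms gap
        ws = detect_windows(ep, stats=UNIT_STATS)
        assert len(ws) == 2

    def test_merge_idempotent(self, rng):
        spans = sorted(rng.integers(0, 2000, size=(8, 2)).tolist())
        windows = [BurstWindow(float(min(a, b)), float(max(a, b) + 1))
                   for a, b in spans]
        once = merge_windows(windows, 25.0)
        twice = merge_windows(once, 25.0)
        assert once == twice

    def test_threshold_monotonicity(self, rng):
        x = np.abs(rng.standard_normal(2601)) * np.linspace(0.5, 3.0, 2601)
        ep = make_epoch(x)
        durations = []
        for thr in (1.5, 2.5, 3.5, 4.5):
            cfg = DetectionConfig(threshold_sd=thr, min_duration_ms=1.0,
                                  merge_gap_ms=1e-6)
            ws = detect_windows(ep, stats=BaselineStats(0.0, 1.0), cfg=cfg)
            durations.append(sum(w.duration_ms for w in ws))
        assert durations == sorted(durations, reverse=True)

    def test_invariant_to_post_press_signal(self):
        ep = window_epoch([(500, 700)], press_time_ms=750.0)
        before = detect_windows(ep, stats=UNIT_STATS)
        ep.samples[0, ep.index_of(800):] = 99.0
        after = detect_windows(ep, stats=UNIT_STATS)
        assert before == after

    def test_zero_baseline_degenerate_threshold(self):
        ep = window_epoch([(600, 700)], value=0.01)
        ws = detect_windows(ep, stats=BaselineStats(0.0, 0.0))
        assert len(ws) == 1  # any nonzero sample exceeds the zero threshold


class TestValidateEpoch:
    def test_single_window_with_onset_inside(self):
        det = validate_epoch(510.0, [BurstWindow(500, 700)])
        assert det.valid and det.reject_reason == "none"
        assert not det.multi_window

    def test_onset_in_early_window_rejected(self):
        det = validate_epoch(210.0, [BurstWindow(200, 260), BurstWindow(500, 700)])
        assert not det.valid
        assert det.reject_reason == REJECT_NOT_LAST_WINDOW
        assert det.multi_window

    def test_no_window(self):
        det = validate_epoch(300.0, [])
        assert not det.valid and det.reject_reason == REJECT_NO_WINDOW

    def test_onset_marginally_before_last_window_ok(self):
        # the IP onset may precede the threshold crossing by a few ms
        det = validate_epoch(497.0, [BurstWindow(500, 700)])
        assert det.valid


class TestDetectPartial:
    def test_silent_channel(self):
        ep = make_epoch(np.zeros(2601), press_time_ms=700.0)
        partial, windows, onset = detect_partial(ep)
        assert partial is False and windows == [] and onset is None

    def test_short_blip_ignored(self):
        ep = make_epoch(np.zeros(2601), press_time_ms=700.0)
        ep.samples[1, ep.index_of(400):ep.index_of(440)] = 5.0
        partial, _, _ = detect_partial(ep, stats=UNIT_STATS)
        assert partial is False

    def test_synthetic_partial_recovered(self, trials_one):
        p = zero_sd_params()
        sub = trials_one[~trials_one.timeout & trials_one.partial].head(40)
        hits = 0
        for k, (_, trial) in enumerate(sub.iterrows()):
            ep = render_epoch(trial, p, rng=500 + k)
            partial, _, onset = detect_partial(ep)
            if partial and abs(onset - ep.meta["partial_onset_ms"]) <= 10.0:
                hits += 1
        assert hits >= 0.95 * len(sub)

    def test_detect_epoch_combines_everything(self, trials_one):
        trial = trials_one[~trials_one.timeout & trials_one.partial].iloc[0]
        ep = render_epoch(trial, rng=3)
        det = detect_epoch(ep)
        assert det.valid
        assert det.partial
        assert abs(det.onset_ms - ep.meta["true_onset_ms"]) <= 2.0
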