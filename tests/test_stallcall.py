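"""No-flow event segmentation, the 15-s blockage rule, and trial summaries."""

import math

import numpy as np
import pytest

import capstall as cs


def make_trace(flux, valid=None, window_s=1.0):
    flux = np.asarray(flux, float)
    n = flux.size
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    speed = np.where(flux > 0, 0.5, np.nan)
    return cs.HemoTrace(window_centers=np.arange(n) * window_s + window_s / 2,
                        flux=flux, speed=speed, valid=valid,
                        window_s=window_s, step_s=window_s)


def brute_force_zero_runs(passage_times, duration, window_s=1.0):
    """Independent oracle: bin ground-truth passage times, scan for zero runs."""
    n = int(math.ceil(duration / window_s))
    counts = np.zeros(n)
    for t in passage_times:
        counts[min(int(t // window_s), n - 1)] += 1
    runs, start = [], None
    for i, c in enumerate(counts):
        if c == 0 and start is None:
            start = i
        elif c > 0 and start is not None:
            runs.append((start * window_s, i * window_s))
            start = None
    if start is not None:
        runs.append((start * window_s, n * window_s))
    return runs


class TestFindStallEvents:
    def test_constant_flux_yields_no_events(self):
        trace = make_trace([5, 4, 6, 5, 7, 5])
        assert cs.find_stall_events(trace, min_gap_s=2.0) == []

    def test_long_zero_run_becomes_one_event(self):
        trace = make_trace([3] * 5 + [0] * 20 + [3] * 5)
        events = cs.find_stall_events(trace, min_gap_s=15.0)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(20.0)
        assert events[0].start_s == pytest.approx(5.0)

    def test_generator_stall_schedule_recovered(self):
        spec = cs.KymoSpec(n_lines=48000, rbc_rate=10.0, noise_sd=0.05,
                           stall_intervals=((5.0, 12.0), (30.0, 48.0)), seed=3)
        image, truth = cs.generate_kymograph(spec)
        kymo = cs.Kymograph(image=image, line_rate=spec.line_rate,
                            pixel_pitch=spec.pixel_pitch)
        trace = cs.compute_hemo_trace(cs.detect_passages(kymo), kymo, window_s=1.0)
        events = cs.find_stall_events(trace, min_gap_s=5.0)

        oracle = brute_force_zero_runs([p.entry_s for p in truth], spec.duration)
        oracle = [(a, b) for a, b in oracle if b - a >= 5.0]
        assert len(events) == len(oracle) == 2
        for ev, (a, b) in zip(events, oracle):
            assert abs(ev.start_s - a) <= 1.0
            assert abs(ev.end_s - b) <= 1.0

    def test_single_invalid_window_bridges_a_run(self):
        valid = np.ones(20, bool)
        valid[10] = False
        flux = np.zeros(20)
        flux[:5] = 3
        flux[10] = 99  # garbage in the invalid window must be ignored
        events = cs.find_stall_events(make_trace(flux, valid), min_gap_s=10.0)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(5.0)
        assert events[0].end_s == pytest.approx(20.0)

    def test_two_consecutive_invalid_windows_split_runs(self):
        valid = np.ones(24, bool)
        valid[10:12] = False
        flux = np.zeros(24)
        events = cs.find_stall_events(make_trace(flux, valid), min_gap_s=5.0)
        assert len(events) == 2

    def test_all_invalid_trace_rejected(self):
        with pytest.raises(ValueError):
            cs.find_stall_events(make_trace([0, 0, 0], valid=[False] * 3),
                                 min_gap_s=1.0)


class TestCallVessel:
    def test_terminal_block_with_zero_flux_verification_is_blocked(self):
        trace = make_trace([5] * 10 + [0] * 20)
        verify = make_trace([0] * 10)
        call = cs.call_vessel(trace, min_block_s=15.0, verify_trace=verify)
        assert call.status == "BLOCKED"
        assert call.confirmed

    def test_midtrace_gap_with_terminal_flow_is_intermittent(self):
        trace = make_trace([5] * 5 + [0] * 10 + [5] * 10)
        call = cs.call_vessel(trace, min_block_s=15.0)
        assert call.status == "INTERMITTENT"

    def test_verification_showing_flow_vetoes_blocked(self):
        trace = make_trace([5] * 10 + [0] * 20)
        verify = make_trace([0, 0, 3, 0])
        call = cs.call_vessel(trace, min_block_s=15.0, verify_trace=verify)
        assert call.status == "INTERMITTENT"
        assert not call.confirmed

    def test_verification_truth_table(self):
        blocked_end = make_trace([5] * 5 + [0] * 20)
        flowing_end = make_trace([5] * 25)
        zero_verify = make_trace([0] * 8)
        flow_verify = make_trace([2] * 8)
        cases = [
            (blocked_end, None, "BLOCKED", False),
            (blocked_end, zero_verify, "BLOCKED", True),
            (blocked_end, flow_verify, "INTERMITTENT", False),
            (flowing_end, None, "FLOWING", False),
            (flowing_end, zero_verify, "FLOWING", True),
        ]
        for trace, verify, status, confirmed in cases:
            call = cs.call_vessel(trace, min_block_s=15.0, verify_trace=verify)
            assert (call.status, call.confirmed) == (status, confirmed)

    def test_lengthening_terminal_gap_never_unblocks(self):
        # monotonicity: once BLOCKED, a longer terminal zero run stays BLOCKED
        for extra in range(0, 20, 4):
            trace = make_trace([5] * 5 + [0] * (15 + extra))
            assert cs.call_vessel(trace, min_block_s=15.0).status == "BLOCKED"

    def test_infinite_min_block_never_blocks(self):
        trace = make_trace([5] * 5 + [0] * 500)
        call = cs.call_vessel(trace, min_block_s=math.inf)
        assert call.status != "BLOCKED"


class TestExcitationSummary:
    @staticmethod
    def _outcome(excitation_s, depth_um=100.0, category="BLOCKAGE"):
        return cs.TrialOutcome(category=category, excitation_s=excitation_s,
                               depth_um=depth_um, group="RoseBengal")

    def test_single_trial_mean_with_undefined_sd(self):
        res = cs.summarize_excitation_times([self._outcome(300.0)],
                                            depth_bins_um=[75, 125])
        (stats,) = res.values()
        assert stats["mean_s"] == 300.0
        assert not stats["sd_defined"]
        assert math.isnan(stats["sd_s"])

    def test_hand_computed_mean_and_sample_sd(self):
        outs = [self._outcome(t) for t in (200.0, 300.0, 400.0)]
        res = cs.summarize_excitation_times(outs, depth_bins_um=[75, 125])
        (stats,) = res.values()
        assert stats["mean_s"] == pytest.approx(300.0)
        assert stats["sd_s"] == pytest.approx(100.0)  # sample SD, ddof=1

    def test_depth_bins_separate_and_empty_bins_omitted(self):
        outs = ([self._outcome(100.0, depth_um=100.0)] * 3
                + [self._outcome(500.0, depth_um=200.0)] * 3
                + [self._outcome(999.0, depth_um=150.0, category="NONE")])
        res = cs.summarize_excitation_times(
            outs, depth_bins_um=[75, 125, 175, 225])
        assert set(res) == {(75.0, 125.0), (175.0, 225.0)}
        assert res[(75.0, 125.0)]["mean_s"] == pytest.approx(100.0)

    def test_generated_trials_recover_spec_mean_within_3_se(self):
        spec = cs.TrialSpec(n_trials={"g": 400}, blockage_prob={"g": 1.0},
                            hemorrhage_prob={"g": 0.0},
                            excitation_mean=295.0, excitation_sd=100.0, seed=5)
        table = cs.generate_trial_table(spec)
        outs = [cs.TrialOutcome("BLOCKAGE", e, d, "g")
                for e, d in zip(table["excitation_s"], table["depth_um"])]
        res = cs.summarize_excitation_times(outs, depth_bins_um=[0, 1000])
        (stats,) = res.values()
        se = 100.0 / math.sqrt(stats["n"])
        assert abs(stats["mean_s"] - 295.0) < 3 * se

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            cs.summarize_excitation_times([], depth_bins_um=[0, 100])
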