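"""Perfusion maps, stallograms and longitudinal insult tracking."""

import dataclasses

import numpy as np
import pytest

import capstall as cs

TP = ["pre", "0h", "2h", "4h", "24h"]


def angios_from(stacks, spec, labels):
    return [cs.compute_angiogram(
        cs.FrameStack(stacks[lab], spec.frame_interval, spec.voxel_size))
        for lab in labels]


class TestComputeAngiogram:
    def test_static_stack_gives_zero_map(self):
        frames = np.broadcast_to(np.random.default_rng(0).random((32, 32)),
                                 (8, 32, 32)).copy()
        angio = cs.compute_angiogram(cs.FrameStack(frames, 0.5))
        assert np.allclose(angio.map, 0.0)

    def test_perfused_voxels_exceed_background_fivefold(self, two_segment_angio):
        stacks, truth = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        angio = angios_from(stacks, two_segment_angio, ["t0"])[0]
        vessel = truth["segment_masks"][0] | truth["segment_masks"][1]
        assert angio.map[vessel].mean() > 5 * angio.map[~vessel].mean()

    def test_linearity_in_dynamic_contrast(self, two_segment_angio):
        # noiseless: doubling the fluctuation amplitude doubles the map
        base = dataclasses.replace(two_segment_angio, noise_sd=0.0,
                                   background_level=2.0, base_vessel_level=3.0)
        double = dataclasses.replace(base, dynamic_contrast=base.dynamic_contrast * 2)
        s1, t1 = cs.generate_angio_timeseries(base, ["t0"])
        s2, t2 = cs.generate_angio_timeseries(double, ["t0"])
        a1 = angios_from(s1, base, ["t0"])[0]
        a2 = angios_from(s2, double, ["t0"])[0]
        vessel = t1["segment_masks"][0]
        interior = a1.map[vessel] > 0
        ratio = a2.map[vessel][interior] / a1.map[vessel][interior]
        assert np.median(ratio) == pytest.approx(2.0, rel=0.05)

    def test_invariant_to_static_offset_image(self, two_segment_angio):
        stacks, _ = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        frames = stacks["t0"]
        offset = np.random.default_rng(1).random(frames.shape[1:])
        a = cs.compute_angiogram(cs.FrameStack(frames, 0.5))
        b = cs.compute_angiogram(cs.FrameStack(frames + offset, 0.5))
        assert np.allclose(a.map, b.map, atol=1e-5)

    def test_rms_method_also_separates_perfused(self, two_segment_angio):
        stacks, truth = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        angio = cs.compute_angiogram(
            cs.FrameStack(stacks["t0"], 0.5), method="rms")
        vessel = truth["segment_masks"][0] | truth["segment_masks"][1]
        assert angio.map[vessel].mean() > 5 * angio.map[~vessel].mean()

    def test_fewer_than_four_frames_rejected(self):
        with pytest.raises(ValueError):
            cs.FrameStack(np.zeros((3, 8, 8)), 0.5)


class TestStallogram:
    def test_vessel_identical_to_background_reads_one_and_stalled(self, rng):
        amap = rng.normal(1.0, 0.05, size=(40, 40)).clip(0)
        angio = cs.Angiogram(map=amap)
        vessel = np.zeros((40, 40), bool)
        vessel[18:22, :] = True
        bg = np.zeros((40, 40), bool)
        bg[5:15, :] = True
        trace = cs.stallogram([angio], vessel, bg)
        assert trace.normalized_intensity[0] == pytest.approx(1.0, abs=0.05)
        assert trace.stalled[0]

    def test_generator_schedule_recovered_as_flags(self, two_segment_angio):
        schedule = [(True, True), (False, True), (False, True), (True, True)]
        stacks, truth = cs.generate_angio_timeseries(
            two_segment_angio, ["a", "b", "c", "d"], schedule)
        angios = angios_from(stacks, two_segment_angio, ["a", "b", "c", "d"])
        vessel = truth["segment_masks"][0] & ~truth["segment_masks"][1]
        bg = ~(truth["segment_masks"][0] | truth["segment_masks"][1])
        trace = cs.stallogram(angios, vessel, bg)
        assert list(trace.stalled) == [False, True, True, False]

    def test_invariant_to_global_gain(self, two_segment_angio):
        stacks, truth = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        angio = angios_from(stacks, two_segment_angio, ["t0"])[0]
        scaled = cs.Angiogram(map=angio.map * 7.3)
        vessel = truth["segment_masks"][0]
        bg = ~(truth["segment_masks"][0] | truth["segment_masks"][1])
        t1 = cs.stallogram([angio], vessel, bg)
        t2 = cs.stallogram([scaled], vessel, bg)
        assert t1.normalized_intensity[0] == pytest.approx(
            t2.normalized_intensity[0], rel=1e-9)
        assert t1.stalled[0] == t2.stalled[0]

    def test_overlapping_rois_rejected(self, two_segment_angio):
        stacks, truth = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        angio = angios_from(stacks, two_segment_angio, ["t0"])[0]
        m = truth["segment_masks"][0]
        with pytest.raises(ValueError):
            cs.stallogram([angio], m, m)


class TestTrackInsult:
    def _run(self, spec, schedule):
        stacks, truth = cs.generate_angio_timeseries(spec, TP, schedule)
        angios = angios_from(stacks, spec, TP)
        vessel = truth["segment_masks"][0] & ~truth["segment_masks"][1]
        bg = ~(truth["segment_masks"][0] | truth["segment_masks"][1])
        return cs.track_insult(list(zip(TP, angios)), vessel, bg)

    def test_block_then_reperfusion_recovered_at_24h(self, two_segment_angio):
        schedule = [(True, True), (False, True), (False, True),
                    (False, True), (True, True)]
        res = self._run(two_segment_angio, schedule)
        assert res["insult_detected"]
        assert res["insult_at"] == "0h"
        assert res["recovered"]
        assert res["recovered_at"] == "24h"

    def test_all_perfused_detects_no_insult(self, two_segment_angio):
        schedule = [(True, True)] * 5
        res = self._run(two_segment_angio, schedule)
        assert not res["insult_detected"]
        assert res["recovered_at"] is None

    def test_fifteen_vessels_all_recover_at_24h(self):
        # cohort mirrors the longitudinal design: blocked 0-4 h, back at 24 h
        recovered = 0
        for seed in range(15):
            spec = cs.AngioSpec(
                volume_shape=(40, 40), voxel_size=2.0,
                vessel_segments=(((10.0, 10.0), (70.0, 70.0), 3.0, True),
                                 ((60.0, 10.0), (10.0, 60.0), 3.0, True)),
                frames_per_timepoint=12, dynamic_contrast=0.5,
                noise_sd=0.05, seed=100 + seed)
            schedule = [(True, True), (False, True), (False, True),
                        (False, True), (True, True)]
            res = self._run(spec, schedule)
            if res["recovered_at"] == "24h":
                recovered += 1
        assert recovered == 15

    def test_single_timepoint_rejected(self, two_segment_angio):
        stacks, truth = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        angio = angios_from(stacks, two_segment_angio, ["t0"])[0]
        with pytest.raises(ValueError):
            cs.track_insult([("t0", angio)], truth["segment_masks"][0],
                            ~truth["segment_masks"][0])


class TestRegistration:
    def test_known_translation_recovered(self, two_segment_angio):
        stacks, _ = cs.generate_angio_timeseries(two_segment_angio, ["t0"])
        angio = angios_from(stacks, two_segment_angio, ["t0"])[0]
        moved = cs.Angiogram(map=np.roll(np.roll(angio.map, 3, 0), -2, 1))
        registered, shift = cs.register_angiograms(angio, moved)
        assert shift[0] == pytest.approx(-3, abs=0.2)
        assert shift[1] == pytest.approx(2, abs=0.2)
        core = (slice(5, -5), slice(5, -5))
        assert np.corrcoef(registered.map[core].ravel(),
                           angio.map[core].ravel())[0, 1] > 0.95


class TestDetectabilityCondition:
    def test_schedule_recovery_across_contrast_grid(self):
        # stalled-flag sequences must equal the schedule whenever the
        # fluctuation amplitude is at least 5x the noise floor
        for contrast, noise in [(0.25, 0.05), (0.5, 0.1), (0.5, 0.05)]:
            spec = cs.AngioSpec(
                volume_shape=(40, 40), voxel_size=2.0,
                vessel_segments=(((10.0, 10.0), (70.0, 70.0), 3.0, True),),
                frames_per_timepoint=12, dynamic_contrast=contrast,
                noise_sd=noise, seed=17)
            schedule = [(True,), (False,), (True,)]
            stacks, truth = cs.generate_angio_timeseries(
                spec, ["a", "b", "c"], schedule)
            angios = angios_from(stacks, spec, ["a", "b", "c"])
            vessel = truth["segment_masks"][0]
            bg = ~vessel
            trace = cs.stallogram(angios, vessel, bg)
            assert list(trace.stalled) == [False, True, False]
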