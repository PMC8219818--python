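import numpy as np
import pandas as pd
import pytest

from scenescale import extract, simulate
from scenescale.schedule import ScanSchedule
from scenescale.simulate import BoldScan, VoxelGroundTruth

from test_simulate import toy_schedule


def make_scan(data, schedule, tr=0.7):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return BoldScan(
        data=data,
        tr_s=tr,
        blank_mask=simulate.blank_mask_for(schedule, data.shape[1], tr),
        schedule=schedule,
    )


class TestDetrend:
    def test_removes_pure_line_and_constant(self):
        sched = toy_schedule([15.0])
        t = np.arange(100, dtype=float)
        scan = make_scan(np.vstack([2.0 + 0.3 * t, np.full(100, 7.0)]), sched)
        out = extract.detrend_linear(scan)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_preserves_sinusoid_up_to_its_own_line(self):
        sched = toy_schedule([15.0])
        t = np.arange(200, dtype=float)
        sine = np.sin(2 * np.pi * t / 23)
        scan = make_scan(5.0 - 0.1 * t + sine, sched)
        out = extract.detrend_linear(scan)
        slope, intercept = np.polyfit(t, sine, 1)
        assert np.allclose(out.data[0], sine - (intercept + slope * t), atol=1e-8)

    def test_too_short_series_rejected(self):
        scan = make_scan(np.ones((1, 2)), toy_schedule([15.0]))
        with pytest.raises(ValueError, match="3 timepoints"):
            extract.detrend_linear(scan)


class TestZScore:
    def test_blank_samples_self_normalize(self):
        sched = toy_schedule([45.0], blank=((0.0, 20.0),))
        rng = np.random.default_rng(0)
        scan = make_scan(rng.normal(50, 5, (3, 120)), sched)
        zs = extract.zscore_blank_baseline(scan)
        blanks = zs.z[:, zs.baseline_mask]
        assert np.allclose(blanks.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(blanks.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_zscore_arithmetic(self):
        # a series whose blanks have mean 100, sd 10: a value of 120 -> z = 2
        sched = toy_schedule([45.0], blank=((0.0, 2.8),))  # TRs 0..3
        data = np.full(100, 120.0)
        data[:4] = [90.0, 110.0, 90.0, 110.0]  # mean 100
        data[:4] = 100.0 + (data[:4] - 100.0) * (10.0 / np.std(data[:4], ddof=1))
        scan = make_scan(data, sched)
        zs = extract.zscore_blank_baseline(scan, washout_trs=0)
        assert np.isclose(zs.baseline_mean[0], 100.0)
        assert np.isclose(zs.baseline_sd[0], 10.0)
        assert np.isclose(zs.z[0, 50], 2.0)

    def test_translation_invariance(self):
        sched = toy_schedule([45.0], blank=((0.0, 20.0),))
        rng = np.random.default_rng(1)
        base = rng.normal(size=(2, 120))
        za = extract.zscore_blank_baseline(make_scan(base, sched))
        zb = extract.zscore_blank_baseline(make_scan(base + 123.4, sched))
        assert np.allclose(za.z, zb.z)

    def test_washout_excludes_start_of_post_block_blanks(self):
        sched = toy_schedule([15.0], blank=((0.0, 7.0), (50.0, 60.0)))
        scan = make_scan(np.random.default_rng(2).normal(size=(1, 120)), sched)
        mask = extract.baseline_mask_for(scan, washout_trs=2)
        times = np.arange(120) * 0.7
        # leading blank fully included; later blank loses its first 2 TRs
        assert mask[(times >= 0) & (times < 7.0)].all()
        in_second = (times >= 50.0) & (times < 60.0)
        first_two = np.flatnonzero(in_second)[:2]
        assert not mask[first_two].any()
        assert mask[np.flatnonzero(in_second)[2:]].all()

    def test_zero_blank_variance_flagged(self):
        sched = toy_schedule([45.0], blank=((0.0, 20.0),))
        scan = make_scan(np.ones((1, 120)), sched)
        with pytest.raises(ValueError, match="variance"):
            extract.zscore_blank_baseline(scan)


class TestEventExtraction:
    def _zs(self, data, sched):
        scan = make_scan(data, sched)
        zs = extract.zscore_blank_baseline(scan, washout_trs=0)
        return zs

    def test_fixed_delay_indexes_onset_plus_seven(self):
        sched = toy_schedule([7.0])  # object onset TR 10
        rng = np.random.default_rng(3)
        data = rng.normal(size=100)
        zs = self._zs(data, sched)
        out = extract.extract_event_responses(zs, 7, onset="object")
        assert np.isclose(out[0, 0], zs.z[0, 17])
        out0 = extract.extract_event_responses(zs, 0, onset="object")
        assert np.isclose(out0[0, 0], zs.z[0, 10])

    def test_scene_onset_reference(self):
        sched = toy_schedule([7.0])  # scene onset 4.5 s -> TR 6
        zs = self._zs(np.random.default_rng(4).normal(size=100), sched)
        out = extract.extract_event_responses(zs, 7, onset="scene")
        assert np.isclose(out[0, 0], zs.z[0, 6 + 7])

    def test_index_past_end_rejected(self):
        sched = toy_schedule([65.0])
        zs = self._zs(np.random.default_rng(5).normal(size=100), sched)
        with pytest.raises(IndexError):
            extract.extract_event_responses(zs, 40, onset="object")

    def test_noise_free_amplitude_recovered_at_true_delay(self):
        sched = toy_schedule([15.0, 45.0], blank=((0.0, 10.0),))
        x = np.array([[1.0, 0, 0, 0], [-1.0, 0, 0, 0]])
        gt = VoxelGroundTruth(weights=(2.0, 0, 0, 0), noise_sd=0.0)
        scan = simulate.simulate_scan(sched, x, [gt], seed=0)
        # add tiny blank jitter so the baseline sd is defined
        rng = np.random.default_rng(0)
        scan.data[:, scan.blank_mask] += rng.normal(0, 1e-6, scan.blank_mask.sum())
        zs = extract.zscore_blank_baseline(scan, washout_trs=0)
        out = extract.extract_event_responses(zs, gt.hrf_peak_delay_trs)
        # z responses stay proportional to the generating amplitudes (3, -1)
        assert np.isclose(out[0, 0] / out[1, 0], -3.0, atol=1e-3)


class TestTopVoxels:
    def _subject_zscores(self, amplitudes, seed=0):
        sched = toy_schedule([20.0, 40.0, 60.0], duration_s=100.0,
                             blank=((0.0, 10.0),))
        gts = [
            VoxelGroundTruth(baseline_event_amplitude=a, noise_sd=0.05)
            for a in amplitudes
        ]
        x = np.zeros((3, 4))
        scan = simulate.simulate_scan(sched, x, gts, seed=seed)
        return [extract.zscore_blank_baseline(scan, washout_trs=0)]

    def test_strongest_voxel_ranked_first(self):
        zs = self._subject_zscores([1.0, 30.0, 1.0, 0.0])
        top = extract.select_top_voxels(zs, k=2)
        assert top.indices[0] == 1
        assert np.all(np.diff(top.scores) <= 0)

    def test_small_roi_keeps_all_voxels(self):
        zs = self._subject_zscores(np.ones(30))
        top = extract.select_top_voxels(zs, k=50)
        assert len(top.indices) == 30

    def test_ties_break_by_voxel_index(self):
        scores = np.array([1.0, 2.0, 2.0, 0.5])
        order = np.argsort(-scores, kind="stable")
        assert list(order[:2]) == [1, 2]  # documents the stable-order contract
        zs = self._subject_zscores([5.0, 5.0, 5.0], seed=1)
        # identical ground truths but independent noise: selection runs
        top = extract.select_top_voxels(zs, k=3)
        assert sorted(top.indices.tolist()) == [0, 1, 2]
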