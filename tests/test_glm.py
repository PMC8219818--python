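import numpy as np
import pandas as pd
import pytest

from scenescale import glm, simulate
from scenescale.simulate import VoxelGroundTruth

from conftest import rank1_fir_dataset
from test_simulate import toy_schedule


class TestRank1Recovery:
    def test_noise_free_outer_product_identifiability(self):
        y, events, slices, h_true, beta_true = rank1_fir_dataset(seed=0)
        fit = glm.fit_r1_glm_fir(y, events, slices, fir_length=12)[0]
        B_est = np.outer(fit.hrf_taps, fit.betas.to_numpy())
        B_true = np.outer(h_true, beta_true)
        rel = np.linalg.norm(B_est - B_true) / np.linalg.norm(B_true)
        assert rel < 1e-6
        assert fit.converged

    def test_normalization_convention(self):
        y, events, slices, *_ = rank1_fir_dataset(seed=1)
        fit = glm.fit_r1_glm_fir(y, events, slices, fir_length=12)[0]
        peak = fit.hrf_taps[np.argmax(np.abs(fit.hrf_taps))]
        assert np.isclose(peak, 1.0)  # unit positive peak; beta carries scale

    def test_all_zero_data_gives_zero_betas(self):
        _, events, slices, *_ = rank1_fir_dataset(seed=2)
        y = np.zeros((1, slices[-1][1]))
        fit = glm.fit_r1_glm_fir(y, events, slices, fir_length=12)[0]
        assert np.allclose(fit.betas.to_numpy(), 0.0)

    def test_single_isolated_event_reads_out_response_window(self):
        # one condition, one event, noise-free: h must be proportional to
        # the event-evoked window read directly from the series
        L = 12
        h_true = simulate.simulate_hrf(
            VoxelGroundTruth(hrf_peak_delay_trs=5), length=L
        )
        T = 120
        onset = 40
        y = np.zeros(T)
        y[onset : onset + L] = 2.5 * h_true
        events = pd.DataFrame({"scan": [0], "onset_tr": [onset],
                               "condition": ["c0"]})
        fit = glm.fit_r1_glm_fir(y[None], events, [(0, T)], fir_length=L)[0]
        window = y[onset : onset + L]
        assert np.allclose(fit.hrf_taps, window / window.max(), atol=1e-8)
        assert np.isclose(fit.betas.iloc[0], window.max(), atol=1e-8)

    def test_rank1_residual_at_least_unconstrained_fir(self):
        # the rank-1 constraint cannot beat the unconstrained FIR fit
        y, events, slices, *_ = rank1_fir_dataset(seed=3, noise_sd=0.5)
        L = 12
        fit = glm.fit_r1_glm_fir(y, events, slices, fir_length=L)[0]
        X, N, conditions = glm._build_design(events, slices, y.shape[1], L)
        D = np.hstack([X, N])
        coef, *_ = np.linalg.lstsq(D, y[0], rcond=None)
        fir_resid = np.linalg.norm(y[0] - D @ coef)
        assert fit.residual_norm >= fir_resid - 1e-8


class TestSingleConditionHrf:
    def _simulated(self, noise_sd, delay=7, seed=0):
        sched = toy_schedule(
            [20.0, 45.0, 70.0, 95.0, 120.0], duration_s=160.0,
            blank=((0.0, 10.0),),
        )
        gt = VoxelGroundTruth(
            weights=(0, 0, 0, 0), baseline_event_amplitude=2.0,
            hrf_peak_delay_trs=delay, noise_sd=noise_sd,
        )
        scan = simulate.simulate_scan(sched, np.zeros((5, 4)), [gt], seed=seed,
                                      offset=0.0)
        onset_trs = np.round(
            sched.trials["object_onset_s"].to_numpy() / 0.7
        ).astype(int)
        events = pd.DataFrame({"scan": 0, "onset_tr": onset_trs,
                               "condition": "all"})
        return scan.data, events

    def test_noise_free_delay_recovery(self):
        data, events = self._simulated(noise_sd=0.0)
        _, delays = glm.fit_single_condition_hrf(data, events,
                                                 [(0, data.shape[1])])
        assert delays[0] == 7

    def test_delta_hrf_recovers_lag(self):
        T = 100
        y = np.zeros(T)
        onsets = [10, 40, 70]
        for o in onsets:
            y[o + 3] = 1.0  # delta response at lag 3
        events = pd.DataFrame({"scan": 0, "onset_tr": onsets,
                               "condition": "all"})
        _, delays = glm.fit_single_condition_hrf(y[None], events, [(0, T)],
                                                 fir_length=10)
        assert delays[0] == 3

    def test_noisy_delay_within_one_tr(self):
        data, events = self._simulated(noise_sd=0.3, delay=8, seed=4)
        _, delays = glm.fit_single_condition_hrf(data, events,
                                                 [(0, data.shape[1])])
        assert abs(int(delays[0]) - 8) <= 1

    def test_labels_do_not_affect_single_condition_fit(self):
        y, events, slices, *_ = rank1_fir_dataset(seed=5, noise_sd=0.2)
        h1, d1 = glm.fit_single_condition_hrf(y, events, slices, fir_length=12)
        shuffled = events.copy()
        shuffled["condition"] = np.random.default_rng(0).permutation(
            events["condition"].to_numpy()
        )
        h2, d2 = glm.fit_single_condition_hrf(y, shuffled, slices,
                                              fir_length=12)
        assert np.array_equal(h1, h2) and np.array_equal(d1, d2)


class TestContrast:
    def test_equal_betas_give_zero(self):
        betas = pd.Series(0.7, index=[f"L{i}" for i in range(1, 7)])
        assert glm.condition_contrast(betas) == pytest.approx(0.0)

    def test_normal_minus_mean_misscaled(self):
        betas = pd.Series([1.0] + [0.8] * 5, index=[f"L{i}" for i in range(1, 7)])
        assert glm.condition_contrast(betas) == pytest.approx(0.2)

    def test_split_mode_one_difference_per_direction(self):
        idx = [f"{d}:L{i}" for d in ("too_small", "too_large")
               for i in range(1, 7)]
        vals = [1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        out = glm.condition_contrast(pd.Series(vals, index=idx),
                                     "split_by_direction")
        assert out["too_small"] == pytest.approx(0.5)
        assert out["too_large"] == pytest.approx(1.0)

    def test_missing_condition_raises(self):
        betas = pd.Series([1.0], index=["L1"])
        with pytest.raises(KeyError, match="missing"):
            glm.condition_contrast(betas)


class TestPermutationTest:
    def _level_dataset(self, effect, seed=0, n_reps=6):
        """Events at 6 levels; level-1 amplitude raised by `effect`."""
        rng = np.random.default_rng(seed)
        L, T_scan = 10, 260
        h = simulate.simulate_hrf(VoxelGroundTruth(hrf_peak_delay_trs=4),
                                  length=L)
        rows, slices, ys = [], [], []
        for s in range(2):
            onsets = np.arange(10, 10 + 13 * 18, 13)[: n_reps * 3]
            levels = rng.permutation(np.tile(np.arange(1, 7), 3))
            sig = np.zeros(T_scan)
            for o, lev in zip(onsets, levels):
                amp = 1.0 + (effect if lev == 1 else 0.0)
                sig[o : o + L] += amp * h
                rows.append({"scan": s, "onset_tr": int(o),
                             "condition": f"L{lev}"})
            slices.append((s * T_scan, (s + 1) * T_scan))
            ys.append(sig + 0.05 * rng.normal(size=T_scan))
        return np.concatenate(ys)[None], pd.DataFrame(rows), slices

    def test_strong_effect_detected(self):
        y, events, slices = self._level_dataset(effect=1.5)
        res = glm.glm_permutation_test(y, events, slices, n_perm=39, seed=1,
                                       fir_length=10)
        assert res.observed > 0
        assert res.p_value <= 0.05

    def test_observed_beyond_all_nulls_gives_zero(self):
        y, events, slices = self._level_dataset(effect=3.0)
        res = glm.glm_permutation_test(y, events, slices, n_perm=19, seed=2,
                                       fir_length=10)
        assert res.p_value == 0.0

    def test_null_effect_not_extreme(self):
        y, events, slices = self._level_dataset(effect=0.0, seed=3)
        res = glm.glm_permutation_test(y, events, slices, n_perm=19, seed=3,
                                       fir_length=10)
        assert res.p_value > 0.05
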