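import numpy as np
import pandas as pd
import pytest

from scenescale import encoding


@pytest.fixture(scope="module")
def session_features(features):
    """Five scans' worth of normalized features (600 events)."""
    return np.vstack([features] * 5)


class TestFitEncoding:
    def test_noise_free_weights_match_ols_oracle(self, session_features):
        X = session_features
        w_true = np.array([2.0, 0.0, 0.0, -1.0])
        y = X @ w_true + 0.3
        fit = encoding.fit_encoding(y, X, ridge_penalty=0.0)
        assert np.allclose(fit.weights[0], w_true, atol=1e-8)
        assert np.isclose(fit.intercepts[0], 0.3, atol=1e-8)
        # independent oracle: unregularized least squares with intercept
        D = np.column_stack([X, np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(fit.weights[0], coef[:4], atol=1e-8)

    def test_feature_independent_responses_give_near_zero_weights(
        self, session_features
    ):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(len(session_features), 50))
        fit = encoding.fit_encoding(y, session_features, 1.0)
        assert np.abs(fit.weights.mean(axis=0)).max() < 0.05

    def test_ridge_shrinkage_monotone(self, session_features):
        rng = np.random.default_rng(1)
        y = session_features @ np.array([1.0, -0.5, 0.3, 0.8]) + rng.normal(
            size=len(session_features)
        )
        norms = [
            np.linalg.norm(encoding.fit_encoding(y, session_features, lam).weights)
            for lam in (0.0, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert np.all(np.diff(norms) <= 1e-12)

    def test_rank_deficient_unpenalized_design_rejected(self):
        X = np.ones((10, 4)) * np.arange(10)[:, None]  # rank 1
        with pytest.raises(ValueError, match="rank"):
            encoding.fit_encoding(np.random.default_rng(2).normal(size=10),
                                  X, ridge_penalty=0.0)


class TestWeightRatios:
    def test_single_feature_voxel_has_ratio_one(self):
        w = np.array([[1.0, 0, 0, 0]])
        assert encoding.selectivity_ratio(w, 0, 1.0) == 1.0

    def test_equal_weights_give_quarter(self):
        w = np.array([[0.5, -0.5, 0.5, -0.5]])
        assert encoding.selectivity_ratio(w, 0, 1.0) == pytest.approx(0.25)

    def test_ratios_sum_to_one_across_features(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(100, 4))
        total = sum(encoding.weight_ratios(w, f) for f in range(4))
        assert np.allclose(total, 1.0)

    def test_all_zero_voxel_excluded_with_warning(self):
        w = np.array([[1.0, 0, 0, 0], [0.0, 0, 0, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            out = encoding.selectivity_ratio(w, 0, 1.0)
        assert out == 1.0

    def test_exchangeable_null_mean_quarter_and_selection_bias(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(4000, 4))  # exchangeable across features
        all_mean = encoding.selectivity_ratio(w, 0, 1.0)
        top_mean = encoding.selectivity_ratio(w, 0, 0.3)
        assert abs(all_mean - 0.25) < 0.01
        assert top_mean > 0.25


class TestResponsiveness:
    def test_strong_tuning_beats_every_permutation(self, session_features):
        rng = np.random.default_rng(5)
        base = session_features @ np.array([-1.0, 0, 0, 0])
        y = base[:, None] + 0.1 * rng.normal(size=(len(session_features), 10))
        res = encoding.responsiveness_test(y, session_features, n_perm=30,
                                           seed=0)
        assert res.p_values["scale_consistency"] == 0.0

    def test_untuned_feature_has_large_p(self, session_features):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(len(session_features), 20))
        res = encoding.responsiveness_test(y, session_features, n_perm=50,
                                           seed=1)
        assert (res.p_values > 0.1).all()


class TestSelectivityPermutation:
    def test_target_tuned_voxels_exceed_null(self, session_features):
        rng = np.random.default_rng(7)
        n_vox = 60
        w = np.zeros((4, n_vox))
        w[0] = rng.normal(-1.0, 0.1, n_vox)  # only scale-consistency tuning
        y = session_features @ w + 0.3 * rng.normal(
            size=(len(session_features), n_vox)
        )
        res = encoding.selectivity_permutation_test(
            y, session_features, target_feature=0, n_perm=30, seed=0
        )
        assert res.observed_ratio > res.null_ratios.max()
        assert res.p_value == 0.0

    def test_null_distribution_sits_above_quarter(self, session_features):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(len(session_features), 200))
        res = encoding.selectivity_permutation_test(
            y, session_features, target_feature=0, n_perm=25, seed=1
        )
        assert res.null_ratios.mean() > 0.25


class TestLoroPrediction:
    def _dataset(self, seed=9, n_vox=8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(250, 4))
        scans = np.repeat(np.arange(5), 50)
        W = rng.normal(size=(n_vox, 4))
        Y = X @ W.T + 0.2 * rng.normal(size=(250, n_vox))
        return Y, X, scans

    def test_held_out_contract(self):
        Y, X, scans = self._dataset()
        a = encoding.predict_bold_loro(Y, X, scans)
        Y2 = Y.copy()
        Y2[scans == 2] += 100.0  # corrupt one scan's responses
        b = encoding.predict_bold_loro(Y2, X, scans)
        # that scan's own predictions are untouched...
        assert np.allclose(a.predicted[scans == 2], b.predicted[scans == 2])
        # ...while other scans' predictions change
        assert not np.allclose(a.predicted[scans == 0], b.predicted[scans == 0])

    def test_run_means_shape(self):
        Y, X, scans = self._dataset()
        pred = encoding.predict_bold_loro(Y, X, scans)
        assert pred.run_voxel_means.shape == (5, Y.shape[1])

    def test_two_scans_required(self):
        Y, X, _ = self._dataset()
        with pytest.raises(ValueError, match="2 scans"):
            encoding.predict_bold_loro(Y, X, np.zeros(250, dtype=int))


class TestGroupTtests:
    def _condition_frame(self, offset_fn, n_subjects=14, seed=10):
        rng = np.random.default_rng(seed)
        cols = pd.MultiIndex.from_product(
            [("too_small", "too_large"), range(1, 7)]
        )
        rows = []
        for _ in range(n_subjects):
            vals = {}
            for d, lev in cols:
                vals[(d, lev)] = offset_fn(lev) + 0.1 * rng.normal()
            rows.append(vals)
        return pd.DataFrame(rows, columns=cols)

    def test_normal_above_misscaled_detected(self):
        df = self._condition_frame(lambda lev: 1.0 if lev == 1 else 0.2)
        out = encoding.prediction_group_ttests(df)
        assert (out["t"] > 3).all()
        assert (out["p_fdr"] < 0.01).all()
        assert (out["df"] == 13).all()

    def test_flat_condition_profile_not_significant(self):
        df = self._condition_frame(lambda lev: 0.0)
        out = encoding.prediction_group_ttests(df)
        assert (out["p"] > 0.05).all()
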