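"""Voxel-wise linear encoding of the four object/scene properties.

A ridge regression per voxel maps the normalized feature matrix (events
x 4 properties, values in [-1, 1]) onto the blank-baseline z responses
extracted at each voxel's HRF peak delay, yielding one feature weight
per property per voxel.  Three inferences follow:

* responsiveness — is the across-voxel mean weight for a property
  different from zero?  Null: refit the full model with feature rows
  shuffled across events (one shared shuffle for all voxels per
  permutation); two-tailed empirical p (smaller tail doubled).
* selectivity — among the top 30% of voxels ranked by the target
  property's absolute weight, the mean ratio |w_target| / sum_f |w_f|.
  With four exchangeable features the all-voxel ratio averages 0.25,
  but ranking-then-averaging biases it upward, so the permutation null
  repeats the ranking and subsetting inside every permutation
  (selection-matched null) before the two-tailed comparison.
* validation — leave-one-run-out predicted responses (weights fit on
  four scans applied to the held-out scan's features), summarized per
  scale-consistency level and mis-scaling direction and tested with
  one-tailed paired t-tests of normal > mean mis-scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FEATURES
from .stats import fdr_bh, paired_t_onetailed, permutation_pvalue


@dataclass
class FeatureWeightSet:
    """Per-voxel feature weights from the encoding model."""

    weights: np.ndarray  # (n_voxels, 4), z units per unit normalized feature
    intercepts: np.ndarray  # (n_voxels,)
    ridge_penalty: float


def fit_encoding(
    event_responses: np.ndarray,
    feature_matrix: np.ndarray,
    ridge_penalty: float = 1.0,
) -> FeatureWeightSet:
    """Ridge regression of every voxel's event responses on the features.

    The penalty acts on the standardized (unit-variance) design scale;
    returned weights are on the original [-1, 1] feature scale.  The
    intercept is unpenalized.  A zero penalty requires a full-rank
    design.
    """
    Y = np.asarray(event_responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(feature_matrix, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"responses {Y.shape} and features {X.shape} must share the event axis"
        )
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    scale = Xc.std(axis=0)
    if np.any(scale == 0):
        raise ValueError("constant feature column in the encoding design")
    Xs = Xc / scale
    if ridge_penalty == 0 and np.linalg.matrix_rank(Xs) < X.shape[1]:
        raise ValueError("rank-deficient design requires a positive ridge penalty")
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    A = Xs.T @ Xs + ridge_penalty * np.eye(X.shape[1])
    W_std = np.linalg.solve(A, Xs.T @ Yc)  # (4, n_voxels)
    W = (W_std / scale[:, None]).T  # back to the original feature scale
    intercepts = y_mean - W @ x_mean
    return FeatureWeightSet(weights=W, intercepts=intercepts, ridge_penalty=ridge_penalty)


@dataclass
class ResponsivenessResult:
    observed_mean: pd.Series  # per feature
    null_means: np.ndarray  # (n_perm, 4)
    p_values: pd.Series  # two-tailed, per feature


def responsiveness_test(
    event_responses: np.ndarray,
    feature_matrix: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    ridge_penalty: float = 1.0,
) -> ResponsivenessResult:
    """Two-tailed permutation test of the mean feature weight per property.

    Every voxel shares the same shuffled feature matrix within a
    permutation; p doubles the proportion of null mean weights at or
    beyond the observed one in the observed direction (e.g. 25/1000
    beyond gives p = .05).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = fit_encoding(event_responses, feature_matrix, ridge_penalty)
    obs_mean = observed.weights.mean(axis=0)
    rng = np.random.default_rng(seed)
    X = np.asarray(feature_matrix, dtype=float)
    null_means = np.empty((n_perm, X.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(X.shape[0])
        null_fit = fit_encoding(event_responses, X[perm], ridge_penalty)
        null_means[i] = null_fit.weights.mean(axis=0)
    p = np.array(
        [
            permutation_pvalue(obs_mean[f], null_means[:, f], tail="two_sided")
            for f in range(X.shape[1])
        ]
    )
    return ResponsivenessResult(
        observed_mean=pd.Series(obs_mean, index=FEATURES),
        null_means=null_means,
        p_values=pd.Series(p, index=FEATURES),
    )


def weight_ratios(weights: np.ndarray, target_feature: int) -> np.ndarray:
    """Per-voxel |w_target| / sum_f |w_f| (NaN for all-zero voxels)."""
    w = np.abs(np.asarray(weights, dtype=float))
    totals = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, w[:, target_feature] / totals, np.nan)


def selectivity_ratio(
    weights: np.ndarray,
    target_feature: int,
    top_fraction: float = 0.3,
) -> float:
    """Mean feature-weight ratio over the top voxels for the target feature.

    Voxels are ranked by |w_target| (descending, ties toward the lower
    index) and the top ``ceil(fraction * n)`` retained; all-zero-weight
    voxels among them are excluded from the mean with a warning.
    """
    w = np.asarray(weights, dtype=float)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_keep = int(np.ceil(top_fraction * w.shape[0]))
    if n_keep < 1:
        raise ValueError("no voxels selected")
    order = np.argsort(-np.abs(w[:, target_feature]), kind="stable")[:n_keep]
    ratios = weight_ratios(w[order], target_feature)
    if np.any(np.isnan(ratios)):
        warnings.warn(
            "all-zero weight vectors excluded from the ratio mean", stacklevel=2
        )
    return float(np.nanmean(ratios))


@dataclass
class SelectivityResult:
    target_feature: str
    top_fraction: float
    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float  # two-tailed


def selectivity_permutation_test(
    event_responses: np.ndarray,
    feature_matrix: np.ndarray,
    target_feature: int = 0,
    top_fraction: float = 0.3,
    n_perm: int = 1000,
    seed: int = 0,
    ridge_penalty: float = 1.0,
) -> SelectivityResult:
    """Selection-matched permutation test of the mean feature-weight ratio.

    Every permutation refits the encoding model on shuffled feature
    rows and repeats the identical top-fraction ranking and ratio
    computation, so the selection-induced upward bias is shared by the
    null and the observed statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed_fit = fit_encoding(event_responses, feature_matrix, ridge_penalty)
    observed = selectivity_ratio(observed_fit.weights, target_feature, top_fraction)
    rng = np.random.default_rng(seed)
    X = np.asarray(feature_matrix, dtype=float)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(X.shape[0])
        fit = fit_encoding(event_responses, X[perm], ridge_penalty)
        nulls[i] = selectivity_ratio(fit.weights, target_feature, top_fraction)
    p = permutation_pvalue(observed, nulls, tail="two_sided")
    return SelectivityResult(
        target_feature=FEATURES[target_feature],
        top_fraction=top_fraction,
        observed_ratio=observed,
        null_ratios=nulls,
        p_value=p,
    )


@dataclass
class EncodingPrediction:
    """Held-out per-event predictions from the LORO encoding model."""

    predicted: np.ndarray  # (n_events, n_voxels)
    scan_ids: np.ndarray
    run_voxel_means: pd.DataFrame  # scan x voxel mean predicted signal


def predict_bold_loro(
    event_responses: np.ndarray,
    feature_matrix: np.ndarray,
    scan_ids: np.ndarray,
    ridge_penalty: float = 1.0,
) -> EncodingPrediction:
    """Leave-one-run-out predicted responses for every event.

    For each scan, weights are fit on the remaining scans' events only
    and applied to the held-out scan's normalized features, so a scan's
    predictions never see its own responses.
    """
    Y = np.asarray(event_responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(feature_matrix, dtype=float)
    scans = np.asarray(scan_ids)
    unique_scans = np.unique(scans)
    if len(unique_scans) < 2:
        raise ValueError("leave-one-run-out needs at least 2 scans")
    predicted = np.empty_like(Y)
    for s in unique_scans:
        test = scans == s
        fit = fit_encoding(Y[~test], X[~test], ridge_penalty)
        predicted[test] = X[test] @ fit.weights.T + fit.intercepts
    run_means = pd.DataFrame(
        {s: predicted[scans == s].mean(axis=0) for s in unique_scans}
    ).T
    return EncodingPrediction(
        predicted=predicted, scan_ids=scans, run_voxel_means=run_means
    )


def condition_means(
    prediction: EncodingPrediction, events: pd.DataFrame
) -> pd.Series:
    """Mean predicted signal per (mis-scaling direction, scale level).

    Averages over voxels and over the events of each of the 12 design
    cells (6 levels x 2 directions); ``events`` rows align with the
    prediction's event axis and carry ``scale_level`` and
    ``misscale_direction`` columns.
    """
    if len(events) != prediction.predicted.shape[0]:
        raise ValueError("events table does not align with predictions")
    signal = prediction.predicted.mean(axis=1)
    df = pd.DataFrame(
        {
            "direction": events["misscale_direction"].to_numpy(),
            "level": events["scale_level"].to_numpy(),
            "signal": signal,
        }
    )
    return df.groupby(["direction", "level"])["signal"].mean()


def normalize_condition_means(cond_means: pd.Series) -> pd.Series:
    """Z-normalize one subject's 12 condition means (mean 0, sd 1)."""
    values = cond_means.to_numpy(dtype=float)
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate condition means (zero variance)")
    return pd.Series((values - values.mean()) / sd, index=cond_means.index)


def prediction_group_ttests(
    subject_condition_means: pd.DataFrame, normalize: bool = True
) -> pd.DataFrame:
    """Group-level one-tailed paired t-tests of normal > mean mis-scaled.

    Parameters
    ----------
    subject_condition_means : DataFrame
        One row per subject, columns a MultiIndex of (direction, level)
        as produced by :func:`condition_means`.
    normalize : bool
        Z-normalize each subject's 12 condition means first.

    Returns
    -------
    DataFrame with one row per mis-scaling direction: t, df, p and
    BH-FDR adjusted p across the tested directions.
    """
    df = subject_condition_means
    if normalize:
        df = df.apply(lambda row: normalize_condition_means(row), axis=1)
    rows = []
    for direction in ("too_small", "too_large"):
        normal = df[(direction, 1)].to_numpy()
        mis = df[[(direction, lev) for lev in range(2, 7)]].mean(axis=1).to_numpy()
        t, dof, p = paired_t_onetailed(normal, mis)
        rows.append({"direction": direction, "t": t, "df": dof, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy()).adjusted
    return out
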