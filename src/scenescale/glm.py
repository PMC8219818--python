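"""Rank-1-constrained GLM with an FIR basis (R1-GLM with FIR).

An unconstrained FIR GLM estimates one coefficient per (lag, condition)
pair.  The rank-1 constraint factorizes that L x K coefficient matrix as

    B = h beta^T,

a single hemodynamic response h (length-L FIR tap vector) shared across
conditions, times one activation coefficient beta_k per condition.  The
factors are estimated per voxel by alternating least squares: given h,
the per-condition regressors are the condition sticks convolved with h
and beta is an ordinary least-squares solve (jointly with per-scan
constant + linear nuisance regressors); given beta, the lag regressors
are beta-weighted sums of shifted sticks and h is the corresponding
solve.  Both steps only touch the precomputed Gram matrix of the full
FIR design, so iterations are cheap and independent of the number of
timepoints.

The returned h is normalized to a unit positive peak; beta carries the
amplitude, and the outer product h beta^T is invariant to that choice.
Running the model with all events as one condition yields the per-voxel
HRF peak delay used by the MVPA and encoding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DEFAULT_FIR_LENGTH, canonical_hrf
from .stats import permutation_pvalue

TASK_CONDITION = "task"


@dataclass
class R1GLMFit:
    """Per-voxel rank-1 FIR fit."""

    hrf_taps: np.ndarray  # (L,), unit positive peak
    betas: pd.Series  # indexed by condition label
    residual_norm: float
    converged: bool
    n_iter: int

    @property
    def peak_delay_trs(self) -> int:
        return int(np.argmax(self.hrf_taps))


def _build_design(
    events: pd.DataFrame,
    scan_slices: list[tuple[int, int]],
    n_timepoints: int,
    fir_length: int,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Dense FIR design X (T x L*K, condition index fastest) and per-scan
    constant + linear nuisance matrix N (T x 2*n_scans)."""
    conditions = sorted(events["condition"].unique())
    k_map = {c: k for k, c in enumerate(conditions)}
    n_cond = len(conditions)
    X = np.zeros((n_timepoints, fir_length * n_cond))
    N = np.zeros((n_timepoints, 2 * len(scan_slices)))
    for s, (t0, t1) in enumerate(scan_slices):
        n_s = t1 - t0
        in_scan = events["scan"] == s
        sticks = np.zeros((n_s, n_cond))
        for onset, cond in zip(
            events.loc[in_scan, "onset_tr"], events.loc[in_scan, "condition"]
        ):
            if not 0 <= onset < n_s:
                raise ValueError(f"event onset TR {onset} outside scan {s}")
            sticks[int(onset), k_map[cond]] += 1.0
        for lag in range(fir_length):
            cols = slice(lag * n_cond, (lag + 1) * n_cond)
            X[t0 + lag : t1, cols] += sticks[: n_s - lag]
        N[t0:t1, 2 * s] = 1.0
        N[t0:t1, 2 * s + 1] = np.linspace(-1, 1, n_s)
    return X, N, conditions


def _als_rank1(
    G: np.ndarray,
    c: np.ndarray,
    yty: float,
    fir_length: int,
    n_cond: int,
    h_init: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Alternating least squares on the Gram system of one voxel."""
    L, K = fir_length, n_cond
    P = G.shape[0] - L * K
    Gxx = G[: L * K, : L * K]
    Gxn = G[: L * K, L * K :]
    Gnn = G[L * K :, L * K :]
    cx, cn = c[: L * K], c[L * K :]
    Gt = Gxx.reshape(L, K, L, K)
    Gxn_t = Gxn.reshape(L, K, P)
    cx_t = cx.reshape(L, K)

    h = h_init.copy()
    beta = np.zeros(K)
    gamma = np.zeros(P)
    B_prev = np.outer(h, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # beta-step: columns are condition sticks convolved with h
        A11 = np.einsum("lkmj,l,m->kj", Gt, h, h)
        A12 = np.einsum("lkp,l->kp", Gxn_t, h)
        rhs = np.concatenate([h @ cx_t, cn])
        A = np.block([[A11, A12], [A12.T, Gnn]])
        sol = _solve(A, rhs)
        beta, gamma = sol[:K], sol[K:]
        if not np.any(beta):
            break  # no signal attributable to any condition
        # h-step: columns are beta-weighted lag regressors
        A11 = np.einsum("lkmj,k,j->lm", Gt, beta, beta)
        A12 = np.einsum("lkp,k->lp", Gxn_t, beta)
        rhs = np.concatenate([cx_t @ beta, cn])
        A = np.block([[A11, A12], [A12.T, Gnn]])
        sol = _solve(A, rhs)
        h, gamma = sol[:L], sol[L:]
        B = np.outer(h, beta)
        denom = max(np.linalg.norm(B_prev), 1e-12)
        if np.linalg.norm(B - B_prev) / denom < tol:
            converged = True
            B_prev = B
            break
        B_prev = B

    theta = np.concatenate([B_prev.reshape(-1), gamma])
    rss = max(yty - 2 * theta @ c + theta @ G @ theta, 0.0)
    # normalization convention: unit positive peak on h, amplitude on beta
    peak = h[np.argmax(np.abs(h))] if np.any(h) else 0.0
    if peak != 0.0:
        h = h / peak
        beta = beta * peak
    return h, beta, float(np.sqrt(rss)), converged, it


def _solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_r1_glm_fir(
    data: np.ndarray,
    events: pd.DataFrame,
    scan_slices: list[tuple[int, int]],
    fir_length: int = DEFAULT_FIR_LENGTH,
    tr_s: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[R1GLMFit]:
    """Fit the rank-1 FIR GLM to every voxel of concatenated scans.

    Parameters
    ----------
    data : ndarray (n_voxels, n_timepoints)
        Concatenated scan time series.
    events : DataFrame with columns ``scan``, ``onset_tr``, ``condition``
        Event onsets in TRs relative to each scan's start, with one
        condition label per event.
    scan_slices : list of (start, stop)
        Row ranges of each scan inside the concatenated time axis.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    X, N, conditions = _build_design(
        events, scan_slices, data.shape[1], fir_length
    )
    D = np.hstack([X, N])
    G = D.T @ D
    C = D.T @ data.T  # (cols, n_voxels)
    h0 = canonical_hrf(length=fir_length, tr_s=tr_s)
    fits = []
    for v in range(data.shape[0]):
        y = data[v]
        h, beta, resid, conv, n_iter = _als_rank1(
            G, C[:, v], float(y @ y), fir_length, len(conditions), h0,
            tol=tol, max_iter=max_iter,
        )
        fits.append(
            R1GLMFit(
                hrf_taps=h,
                betas=pd.Series(beta, index=conditions),
                residual_norm=resid,
                converged=conv,
                n_iter=n_iter,
            )
        )
    return fits


def fit_single_condition_hrf(
    data: np.ndarray,
    events: pd.DataFrame,
    scan_slices: list[tuple[int, int]],
    fir_length: int = DEFAULT_FIR_LENGTH,
    tr_s: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel HRF estimate with all events combined into one condition.

    Returns
    -------
    (hrfs, peak_delays) : (n_voxels, L) taps and (n_voxels,) argmax delays.
    """
    ev = events.copy()
    ev["condition"] = "all"
    fits = fit_r1_glm_fir(data, ev, scan_slices, fir_length, tr_s)
    hrfs = np.stack([f.hrf_taps for f in fits])
    delays = np.array([f.peak_delay_trs for f in fits])
    return hrfs, delays


def condition_labels(
    stim_events: pd.DataFrame, mode: str = "pooled_6level"
) -> pd.Series:
    """Condition labels from stimulus-event ``scale_level`` (and
    ``misscale_direction`` in split mode)."""
    if mode == "pooled_6level":
        return stim_events["scale_level"].map(lambda s: f"L{int(s)}")
    if mode == "split_by_direction":
        return (
            stim_events["misscale_direction"]
            + ":"
            + stim_events["scale_level"].map(lambda s: f"L{int(s)}")
        )
    raise ValueError(f"unknown mode {mode!r}")


def condition_contrast(mean_betas: pd.Series, mode: str = "pooled_6level"):
    """Normal-minus-mis-scaled amplitude difference.

    In pooled mode, returns beta(level 1) minus the mean beta over
    levels 2-6.  In split mode, returns one such difference per
    mis-scaling direction.  A task condition, if present, is ignored.
    """
    betas = mean_betas.drop(TASK_CONDITION, errors="ignore")

    def _diff(sub: pd.Series, prefix: str = "") -> float:
        normal = f"{prefix}L1"
        mis = [f"{prefix}L{i}" for i in range(2, 7)]
        missing = [c for c in [normal, *mis] if c not in sub.index]
        if missing:
            raise KeyError(f"missing condition(s): {missing}")
        return float(sub[normal] - sub[mis].mean())

    if mode == "pooled_6level":
        return _diff(betas)
    if mode == "split_by_direction":
        return {
            d: _diff(betas, prefix=f"{d}:") for d in ("too_small", "too_large")
        }
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class GLMGroupResult:
    """Observed contrast with its permutation null."""

    mean_betas: pd.Series
    observed: "float | dict[str, float]"
    null_values: "np.ndarray | dict[str, np.ndarray]"
    p_value: "float | dict[str, float]"


def glm_permutation_test(
    data: np.ndarray,
    events: pd.DataFrame,
    scan_slices: list[tuple[int, int]],
    mode: str = "pooled_6level",
    n_perm: int = 1000,
    seed: int = 0,
    fir_length: int = DEFAULT_FIR_LENGTH,
    tr_s: float = 0.7,
) -> GLMGroupResult:
    """One-tailed permutation test of the normal-vs-mis-scaled contrast.

    Condition labels are permuted across stimulus events (task events
    keep their label) and the full R1-GLM + voxel-averaging + contrast
    pipeline is re-run per permutation; p is the proportion of null
    differences at or above the observed one, with no +1 smoothing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def _contrast(ev: pd.DataFrame):
        fits = fit_r1_glm_fir(data, ev, scan_slices, fir_length, tr_s)
        mean_betas = pd.concat([f.betas for f in fits], axis=1).mean(axis=1)
        return mean_betas, condition_contrast(mean_betas, mode)

    mean_betas, observed = _contrast(events)
    rng = np.random.default_rng(seed)
    permutable = (events["condition"] != TASK_CONDITION).to_numpy()
    labels = events["condition"].to_numpy().copy()
    nulls = []
    for _ in range(n_perm):
        perm_labels = labels.copy()
        perm_labels[permutable] = rng.permutation(labels[permutable])
        ev = events.copy()
        ev["condition"] = perm_labels
        nulls.append(_contrast(ev)[1])

    if mode == "pooled_6level":
        null_arr = np.array(nulls)
        p = permutation_pvalue(observed, null_arr, tail="greater")
        return GLMGroupResult(mean_betas, observed, null_arr, p)
    null_dict = {
        d: np.array([n[d] for n in nulls]) for d in ("too_small", "too_large")
    }
    p = {
        d: permutation_pvalue(observed[d], null_dict[d], tail="greater")
        for d in null_dict
    }
    return GLMGroupResult(mean_betas, observed, null_dict, p)
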