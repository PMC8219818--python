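"""Per-scan response extraction.

The pipeline removes a linear trend from every voxel's time series,
z-scores each scan against its own blank-period baseline,

    z_n = (d_n - b) / s_b,

with b and s_b the mean and standard deviation of the scan's blank TRs
(the first two TRs of each post-block blank are excluded as a
hemodynamic washout), and then reads out one value per event at the
event-onset TR plus an HRF peak delay — either a fixed 7-TR (4.9 s)
delay, used when ranking voxels by their mean scene-onset response, or
a per-voxel delay estimated from the data, used for the MVPA and
encoding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _scipy_detrend

from .simulate import BoldScan

FIXED_PEAK_DELAY_TRS = 7  # 7 TRs x 0.7 s = 4.9 s
BLANK_WASHOUT_TRS = 2


def detrend_linear(scan: BoldScan) -> BoldScan:
    """Remove each voxel's ordinary-least-squares line over the full scan."""
    if scan.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    detrended = _scipy_detrend(scan.data, axis=1, type="linear")
    return BoldScan(
        data=detrended,
        tr_s=scan.tr_s,
        blank_mask=scan.blank_mask,
        schedule=scan.schedule,
        ground_truths=scan.ground_truths,
    )


@dataclass
class ZScoreSeries:
    """Blank-baseline z-scored series for one scan."""

    z: np.ndarray  # (n_voxels, n_timepoints)
    baseline_mean: np.ndarray  # (n_voxels,)
    baseline_sd: np.ndarray  # (n_voxels,)
    baseline_mask: np.ndarray  # (n_timepoints,) bool, after washout
    tr_s: float
    schedule: "object"


def baseline_mask_for(scan: BoldScan, washout_trs: int = BLANK_WASHOUT_TRS) -> np.ndarray:
    """Blank-period TR mask with the first ``washout_trs`` TRs of each
    post-block blank excluded (the leading blank needs no washout)."""
    times = np.arange(scan.n_timepoints) * scan.tr_s
    mask = np.zeros(scan.n_timepoints, dtype=bool)
    for start, end in scan.schedule.blank_periods:
        eff_start = start if start == 0.0 else start + washout_trs * scan.tr_s
        mask |= (times >= eff_start) & (times < end)
    return mask


def zscore_blank_baseline(
    scan: BoldScan, washout_trs: int = BLANK_WASHOUT_TRS
) -> ZScoreSeries:
    """Z-score a (detrended) scan against its blank-period baseline."""
    mask = baseline_mask_for(scan, washout_trs)
    if mask.sum() < 2:
        raise ValueError("need at least 2 blank timepoints for a baseline")
    blanks = scan.data[:, mask]
    b = blanks.mean(axis=1)
    s_b = blanks.std(axis=1, ddof=1)
    if np.any(s_b == 0):
        bad = np.flatnonzero(s_b == 0).tolist()
        raise ValueError(f"zero blank-period variance in voxel(s) {bad}")
    z = (scan.data - b[:, None]) / s_b[:, None]
    return ZScoreSeries(
        z=z,
        baseline_mean=b,
        baseline_sd=s_b,
        baseline_mask=mask,
        tr_s=scan.tr_s,
        schedule=scan.schedule,
    )


def extract_event_responses(
    zscores: ZScoreSeries,
    delays_per_voxel: np.ndarray | int,
    onset: str = "object",
    trial_type: str = "stimulus",
) -> np.ndarray:
    """Per-event z responses at onset TR + peak delay.

    Parameters
    ----------
    delays_per_voxel : int or array (n_voxels,)
        HRF peak delay in TRs; a scalar applies the same fixed delay
        (e.g. 7 TRs) to every voxel.
    onset : "object" or "scene"
        Which event reference to index from: the object onset (used for
        MVPA/encoding responses) or the scene onset (used for top-voxel
        selection).

    Returns
    -------
    ndarray (n_events, n_voxels)
    """
    n_voxels, n_t = zscores.z.shape
    delays = np.broadcast_to(np.asarray(delays_per_voxel, dtype=int), (n_voxels,))
    if np.any(delays < 0):
        raise ValueError("delays must be >= 0")
    trials = zscores.schedule.trials
    trials = trials[trials["trial_type"] == trial_type]
    col = "object_onset_s" if onset == "object" else "onset_s"
    onset_trs = np.round(trials[col].to_numpy() / zscores.tr_s).astype(int)
    idx = onset_trs[:, None] + delays[None, :]  # (events, voxels)
    if idx.max() >= n_t:
        raise IndexError("event onset + delay indexes past the end of the scan")
    return zscores.z[np.arange(n_voxels)[None, :], idx]


@dataclass
class TopVoxelSet:
    """Indices of the most scene-responsive voxels, highest score first."""

    indices: np.ndarray
    scores: np.ndarray  # mean scene-onset z, non-increasing


def select_top_voxels(
    zscores_per_scan: list[ZScoreSeries],
    k: int = 50,
    fixed_delay_trs: int = FIXED_PEAK_DELAY_TRS,
) -> TopVoxelSet:
    """Top-k voxels by mean scene-onset z across all events and scans.

    Uses the fixed 7-TR peak delay; all voxels are kept if the region
    has fewer than k.  Ties break toward the lower voxel index.
    """
    if not zscores_per_scan:
        raise ValueError("need at least one scan")
    means = np.mean(
        [
            extract_event_responses(zs, fixed_delay_trs, onset="scene").mean(axis=0)
            for zs in zscores_per_scan
        ],
        axis=0,
    )
    order = np.argsort(-means, kind="stable")[: min(k, len(means))]
    return TopVoxelSet(indices=order, scores=means[order])
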