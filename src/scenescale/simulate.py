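"""Synthetic BOLD time series with known ground-truth feature tuning.

Each voxel responds to every object onset with an amplitude that is
linear in the four normalized stimulus properties,

    a_e = baseline + sum_f w_f * x_{e,f}        (stimulus trials)
    a_e = baseline                              (task trials, no object)

The amplitude scales a stick series at the object-onset TRs, which is
convolved with a voxel-specific hemodynamic response function (a gamma
kernel with a small undershoot, unit peak at a configurable delay).
Linear drift, a constant offset and Gaussian noise (optionally AR(1))
are added.  Everything is reproducible from a seed, and the generating
weights are carried along so that downstream estimators can be checked
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import ScanSchedule

DEFAULT_TR_S = 0.7
DEFAULT_FIR_LENGTH = 20  # taps; 14 s at TR = 0.7 s


@dataclass(frozen=True)
class VoxelGroundTruth:
    """Generative parameters of one synthetic voxel.

    ``weights`` are signal units per unit normalized feature (column
    order as in :data:`scenescale.design.FEATURES`);
    ``baseline_event_amplitude`` is the feature-independent response to
    any event; ``hrf_peak_delay_trs`` the tap index of the HRF peak;
    ``noise_sd`` the marginal noise standard deviation; ``drift_slope``
    signal units per TR; ``ar1_coef`` in [0, 1).
    """

    weights: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    baseline_event_amplitude: float = 1.0
    hrf_peak_delay_trs: int = 7
    hrf_shape: str = "gamma"  # or "delta"
    hrf_sharpness: float = 6.0
    hrf_undershoot: float = 0.1
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    ar1_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hrf_peak_delay_trs < 1:
            raise ValueError("hrf_peak_delay_trs must be >= 1")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")


def simulate_hrf(
    ground_truth: VoxelGroundTruth,
    length: int = DEFAULT_FIR_LENGTH,
    tr_s: float = DEFAULT_TR_S,
) -> np.ndarray:
    """FIR tap vector of the voxel's HRF (unit positive peak at the delay).

    The default shape is a gamma bump minus a delayed, shallower gamma
    undershoot; ``hrf_shape="delta"`` gives a single unit tap.
    """
    delay = ground_truth.hrf_peak_delay_trs
    if delay >= length:
        raise ValueError(f"peak delay {delay} must be < FIR length {length}")
    if ground_truth.hrf_shape == "delta":
        h = np.zeros(length)
        h[delay] = 1.0
        return h
    t = np.arange(length, dtype=float) * tr_s
    tp = delay * tr_s
    a = ground_truth.hrf_sharpness
    with np.errstate(divide="ignore", invalid="ignore"):
        bump = np.where(t > 0, (t / tp) ** a * np.exp(a * (1 - t / tp)), 0.0)
        tu = 1.9 * tp
        under = np.where(t > 0, (t / tu) ** (2 * a) * np.exp(2 * a * (1 - t / tu)), 0.0)
    h = bump - ground_truth.hrf_undershoot * under
    h = h / h.max()
    if int(np.argmax(h)) != delay:  # undershoot strong enough to move the peak
        raise ValueError("HRF shape parameters moved the peak off the delay")
    return h


def canonical_hrf(length: int = DEFAULT_FIR_LENGTH, tr_s: float = DEFAULT_TR_S,
                  peak_delay_s: float = 4.9) -> np.ndarray:
    """Canonical gamma HRF sampled at TR resolution (peak ~4.9 s)."""
    gt = VoxelGroundTruth(hrf_peak_delay_trs=max(1, round(peak_delay_s / tr_s)))
    return simulate_hrf(gt, length=length, tr_s=tr_s)


@dataclass
class BoldScan:
    """Voxels x timepoints signal matrix for one scan.

    ``blank_mask`` is True exactly at TRs whose acquisition time falls
    inside a scheduled blank period.  ``ground_truths`` is attached for
    synthetic data only.
    """

    data: np.ndarray  # (n_voxels, n_timepoints)
    tr_s: float
    blank_mask: np.ndarray  # (n_timepoints,) bool
    schedule: ScanSchedule
    ground_truths: list[VoxelGroundTruth] | None = None

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def to_nifti(self, voxel_size_mm: float = 2.0):
        """Export as a 4D NIfTI image (1 x 1 x V x T) for interoperability."""
        import nibabel as nib

        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.data[None, None, :, :].astype(np.float32), affine)
        img.header["pixdim"][4] = self.tr_s
        return img


def blank_mask_for(schedule: ScanSchedule, n_timepoints: int, tr_s: float) -> np.ndarray:
    """Boolean per-TR mask of the schedule's blank periods."""
    times = np.arange(n_timepoints) * tr_s
    mask = np.zeros(n_timepoints, dtype=bool)
    for start, end in schedule.blank_periods:
        mask |= (times >= start) & (times < end)
    return mask


def simulate_scan(
    schedule: ScanSchedule,
    feature_matrix: np.ndarray,
    ground_truths: list[VoxelGroundTruth],
    seed: int,
    tr_s: float = DEFAULT_TR_S,
    fir_length: int = DEFAULT_FIR_LENGTH,
    offset: float = 100.0,
) -> BoldScan:
    """Simulate one scan's BOLD matrix from the schedule and ground truths.

    ``feature_matrix`` rows must align with the schedule's stimulus
    trials (in presentation order).  Object onsets are mapped to the TR
    grid by rounding to the nearest TR; overlapping responses sum
    linearly.
    """
    stim = schedule.stimulus_trials
    features = np.asarray(feature_matrix, dtype=float)
    if features.shape != (len(stim), 4):
        raise ValueError(
            f"feature matrix shape {features.shape} does not align with "
            f"{len(stim)} stimulus trials"
        )
    n_t = int(np.ceil(schedule.scan_duration_s / tr_s))
    rng = np.random.default_rng(seed)

    onset_trs = np.round(
        schedule.trials["object_onset_s"].to_numpy() / tr_s
    ).astype(int)
    is_stim = (schedule.trials["trial_type"] == "stimulus").to_numpy()
    t_index = np.arange(n_t, dtype=float)

    data = np.empty((len(ground_truths), n_t))
    for v, gt in enumerate(ground_truths):
        amps = np.full(len(schedule.trials), gt.baseline_event_amplitude)
        amps[is_stim] += features @ np.asarray(gt.weights, dtype=float)
        sticks = np.zeros(n_t)
        np.add.at(sticks, onset_trs, amps)
        hrf = simulate_hrf(gt, length=fir_length, tr_s=tr_s)
        signal = np.convolve(sticks, hrf)[:n_t]
        noise = rng.normal(0.0, 1.0, n_t)
        if gt.ar1_coef > 0:
            # AR(1) innovation scaling keeps the marginal sd at noise_sd
            from scipy.signal import lfilter

            noise = lfilter([1.0], [1.0, -gt.ar1_coef], noise) * np.sqrt(
                1 - gt.ar1_coef**2
            )
        data[v] = offset + signal + gt.drift_slope * t_index + gt.noise_sd * noise

    return BoldScan(
        data=data,
        tr_s=tr_s,
        blank_mask=blank_mask_for(schedule, n_t, tr_s),
        schedule=schedule,
        ground_truths=list(ground_truths),
    )


def make_ground_truths(
    n_voxels: int,
    scenario: str,
    seed: int,
    noise_sd: float = 1.0,
) -> list[VoxelGroundTruth]:
    """Draw a heterogeneous set of voxel ground truths for one "ROI".

    Scenarios
    ---------
    ``"null"``
        All feature weights zero; responses carry only the baseline
        event amplitude.
    ``"scale_negative"``
        Scale-consistency weights drawn around -0.6 (activity falls with
        increasing mis-scaling), other features weakly and symmetrically
        tuned.  Emulates a scene-selective region like TOS.
    ``"heterogeneous"``
        A quarter of voxels null; the rest each prefer one random
        feature (scale-consistency preference drawn negative), to
        exercise top-voxel selection.
    """
    rng = np.random.default_rng(seed)
    gts = []
    for _ in range(n_voxels):
        base = rng.uniform(0.8, 1.2)
        delay = int(rng.integers(6, 9))
        drift = rng.normal(0.0, 0.003)
        if scenario == "null":
            w = np.zeros(4)
        elif scenario == "scale_negative":
            w = rng.normal(0.0, 0.05, 4)
            w[0] = rng.normal(-0.6, 0.1)
        elif scenario == "heterogeneous":
            w = rng.normal(0.0, 0.05, 4)
            if rng.random() > 0.25:
                pref = int(rng.integers(4))
                mag = rng.normal(0.6, 0.15)
                w[pref] = -abs(mag) if pref == 0 else np.sign(rng.normal()) * abs(mag)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        gts.append(
            VoxelGroundTruth(
                weights=tuple(w),
                baseline_event_amplitude=base,
                hrf_peak_delay_trs=delay,
                noise_sd=noise_sd,
                drift_slope=drift,
            )
        )
    return gts
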