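import numpy as np
import pandas as pd
import pytest

from scenescale import pipeline


@pytest.fixture(scope="session")
def images():
    """The 120-image factorial set with property levels attached."""
    imgs, _ = pipeline.build_design()
    return imgs


@pytest.fixture(scope="session")
def features(images):
    from scenescale import design

    return design.feature_matrix(images)


@pytest.fixture(scope="session")
def session_features_acc(features):
    """Features for a full 5-scan session (600 events)."""
    return np.vstack([features] * 5)


@pytest.fixture(scope="session")
def tuned_subject(images):
    """One simulated subject with negative scale-consistency tuning."""
    cfg = pipeline.PipelineConfig(
        n_subjects=1, n_voxels=12, scenario="scale_negative", seed=11
    )
    data = pipeline.simulate_subject(images, cfg, 0)
    analysis = pipeline.prepare_subject(data, images, cfg)
    return cfg, data, analysis


def rank1_fir_dataset(seed=0, L=12, K=4, n_scans=2, T=300, n_events=40,
                      noise_sd=0.0):
    """Noise-free (or noisy) data generated exactly from the rank-1 model:
    known h* (unit peak) and per-condition amplitudes beta*."""
    from scenescale import simulate

    rng = np.random.default_rng(seed)
    h_true = simulate.simulate_hrf(
        simulate.VoxelGroundTruth(hrf_peak_delay_trs=5), length=L
    )
    beta_true = np.array([1.0, -0.5, 2.0, 0.7])[:K]
    rows, slices, ys = [], [], []
    for s in range(n_scans):
        onsets = np.sort(
            rng.choice(np.arange(5, T - L - 1), n_events, replace=False)
        )
        conds = rng.integers(0, K, n_events)
        sig = np.zeros(T)
        for o, c in zip(onsets, conds):
            sig[o : o + L] += beta_true[c] * h_true
            rows.append({"scan": s, "onset_tr": int(o), "condition": f"c{c}"})
        slices.append((s * T, (s + 1) * T))
        ys.append(sig + 3.0 + noise_sd * rng.normal(size=T))
    y = np.concatenate(ys)[None, :]
    return y, pd.DataFrame(rows), slices, h_true, beta_true
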