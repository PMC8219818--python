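"""Voxel-wise encoding model: feature weights, responsiveness, selectivity.

Fits the ridge encoding model to simulated event responses, tests
per-property responsiveness (mean weight vs a shuffled-feature null)
and scale-consistency selectivity (top-30% feature-weight ratio vs a
selection-matched null), and reports the chance calibration of the
ratio statistic.  Null distributions are written in a long, plotting-
ready format.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scenescale import encoding
from scenescale.design import FEATURES
from scenescale.pipeline import (
    PipelineConfig,
    build_design,
    prepare_subject,
    simulate_subject,
)

OUT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 200


def main() -> None:
    OUT.mkdir(exist_ok=True)
    images, features = build_design()
    cfg = PipelineConfig(n_subjects=1, n_voxels=40, scenario="scale_negative",
                         seed=4)
    ana = prepare_subject(simulate_subject(images, cfg, 0), images, cfg)

    fit = encoding.fit_encoding(ana.responses, ana.features, cfg.ridge_penalty)
    mean_w = pd.Series(fit.weights.mean(axis=0), index=FEATURES)
    print("mean feature weights (z units per unit normalized feature):")
    print(mean_w.round(3).to_string())

    resp = encoding.responsiveness_test(
        ana.responses, ana.features, n_perm=N_PERM, seed=5,
        ridge_penalty=cfg.ridge_penalty,
    )
    print(f"\nresponsiveness (two-tailed, {N_PERM} shuffled-feature "
          "permutations):")
    print(resp.p_values.round(3).to_string())

    sel = encoding.selectivity_permutation_test(
        ana.responses, ana.features, target_feature=0,
        top_fraction=cfg.top_fraction, n_perm=N_PERM, seed=6,
        ridge_penalty=cfg.ridge_penalty,
    )
    print(
        f"\nscale-consistency selectivity: top-30% ratio {sel.observed_ratio:.3f} "
        f"vs selection-matched null mean {sel.null_ratios.mean():.3f} "
        f"(p = {sel.p_value:.3f})"
    )

    # chance calibration: all-voxel ratio under a feature-independent null
    rng = np.random.default_rng(7)
    X5 = np.vstack([features] * 5)
    null_fit = encoding.fit_encoding(rng.normal(size=(len(X5), 2000)), X5,
                                     cfg.ridge_penalty)
    calib = float(np.nanmean(encoding.weight_ratios(null_fit.weights, 0)))
    print(f"\nall-voxel null ratio calibration: {calib:.3f} "
          "(1/4 under exchangeable tuning; design correlations pull the "
          "feature-independent value slightly below)")

    long = pd.concat(
        [
            pd.DataFrame({"statistic": "selectivity_ratio",
                          "value": sel.null_ratios}),
            pd.DataFrame({"statistic": "mean_weight_scale_consistency",
                          "value": resp.null_means[:, 0]}),
        ],
        ignore_index=True,
    )
    long.to_csv(OUT / "encoding_null_distributions.tsv", sep="\t", index=False)
    pd.DataFrame(fit.weights, columns=FEATURES).to_csv(
        OUT / "encoding_weights_subject0.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
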