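"""Group-level LORO-CV validation of the encoding model.

For 14 simulated subjects, predicts held-out BOLD responses from
encoding weights fit on the other four scans, averages the predictions
per scale-consistency level and mis-scaling direction, and tests
whether the normal scale level exceeds the mean of the mis-scaled
levels in each direction (one-tailed paired t-tests, BH-FDR).  Run for
a generator with negative scale-consistency tuning and for a null
generator.
"""

from pathlib import Path

import pandas as pd

from scenescale import encoding
from scenescale.pipeline import (
    PipelineConfig,
    build_design,
    prepare_subject,
    simulate_subject,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def group_validation(scenario: str, seed: int = 0, n_subjects: int = 14):
    images, _ = build_design()
    cfg = PipelineConfig(n_subjects=n_subjects, n_voxels=36,
                         scenario=scenario, seed=seed)
    rows = []
    for s in range(n_subjects):
        ana = prepare_subject(simulate_subject(images, cfg, s), images, cfg)
        pred = encoding.predict_bold_loro(
            ana.responses, ana.features, ana.events["scan"].to_numpy(),
            cfg.ridge_penalty,
        )
        rows.append(encoding.condition_means(pred, ana.events).rename(s))
    cond = pd.DataFrame(rows)
    return cond, encoding.prediction_group_ttests(cond)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for scenario in ("scale_negative", "null"):
        cond, tests = group_validation(scenario)
        cond.to_csv(OUT / f"predicted_condition_means_{scenario}.tsv", sep="\t")
        tests.to_csv(OUT / f"prediction_ttests_{scenario}.tsv", sep="\t",
                     index=False)
        print(f"\n{scenario} generator (n = 14 subjects):")
        print(tests.round(4).to_string(index=False))
        sig = (tests["p_fdr"] < 0.05).sum()
        print(
            f"normal > mis-scaled significant in {sig}/2 directions"
            + (" — reproduces the qualitative pattern" if sig == 2 else "")
        )


if __name__ == "__main__":
    main()
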