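"""Rank-1 FIR GLM contrasts: normal vs mis-scaled amplitudes.

Fits the condition-wise R1-GLM (six scale-consistency levels, then the
levels split by mis-scaling direction) on simulated subjects with
negative scale-consistency tuning, and runs a small label-permutation
test of the normal-minus-mis-scaled contrast for the first subject.
"""

from pathlib import Path

import pandas as pd

from scenescale import glm
from scenescale.pipeline import (
    PipelineConfig,
    build_design,
    prepare_subject,
    simulate_subject,
    subject_glm_contrasts,
)

OUT = Path(__file__).resolve().parent.parent / "results"
N_SUBJECTS = 4
N_PERM = 99  # demonstration-scale null


def main() -> None:
    OUT.mkdir(exist_ok=True)
    images, _ = build_design()
    cfg = PipelineConfig(n_subjects=N_SUBJECTS, n_voxels=24,
                         scenario="scale_negative", seed=1)
    rows, analyses = [], []
    for s in range(N_SUBJECTS):
        ana = prepare_subject(simulate_subject(images, cfg, s), images, cfg)
        analyses.append(ana)
        _, pooled = subject_glm_contrasts(ana, cfg, "pooled_6level")
        _, split = subject_glm_contrasts(ana, cfg, "split_by_direction")
        rows.append({"subject": s, "pooled": pooled, **split})
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(OUT / "glm_contrasts.tsv", sep="\t", index=False)
    print("normal-minus-mis-scaled contrasts (voxel-mean betas, z units):")
    print(contrasts.round(3).to_string(index=False))

    ana = analyses[0]
    ev = ana.glm_events.copy()
    stim = ev["trial_type"] == "stimulus"
    ev["condition"] = glm.TASK_CONDITION
    ev.loc[stim, "condition"] = glm.condition_labels(ev.loc[stim],
                                                     "pooled_6level")
    res = glm.glm_permutation_test(
        ana.z_data, ev, ana.scan_slices, mode="pooled_6level",
        n_perm=N_PERM, seed=2, fir_length=cfg.fir_length, tr_s=cfg.tr_s,
    )
    print(
        f"\nsubject 0 permutation test ({N_PERM} label permutations): "
        f"observed difference {res.observed:.3f}, one-tailed p = {res.p_value:.3f}"
    )
    print("(positive difference = higher amplitude for normally scaled objects)")


if __name__ == "__main__":
    main()
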