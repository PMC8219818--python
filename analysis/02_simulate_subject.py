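"""Simulate one subject's session and extract event responses.

Generates five ~10.5 min scans (TR 0.7 s) for a subject whose voxels
carry negative scale-consistency tuning, runs the extraction chain
(linear detrend, blank-baseline z-scoring, single-condition rank-1 FIR
GLM for per-voxel HRF peak delays, per-event response read-out), and
writes the event-response table plus the generating ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scenescale.pipeline import PipelineConfig, build_design, prepare_subject, simulate_subject

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    images, _ = build_design()
    cfg = PipelineConfig(n_subjects=1, n_voxels=40, scenario="scale_negative",
                         seed=0)
    data = simulate_subject(images, cfg, 0)
    analysis = prepare_subject(data, images, cfg)

    truth = pd.DataFrame(
        {
            "voxel": np.arange(cfg.n_voxels),
            "true_peak_delay_trs": [g.hrf_peak_delay_trs for g in data.ground_truths],
            "est_peak_delay_trs": analysis.peak_delays,
            **{
                f"w_{i}": [g.weights[i] for g in data.ground_truths]
                for i in range(4)
            },
        }
    )
    truth.to_csv(OUT / "subject0_ground_truth.tsv", sep="\t", index=False)

    resp = pd.DataFrame(
        analysis.responses, columns=[f"v{j}" for j in range(cfg.n_voxels)]
    )
    pd.concat([analysis.events, resp], axis=1).to_csv(
        OUT / "subject0_event_responses.tsv", sep="\t", index=False
    )

    n_scans = len(data.scans)
    n_t = data.scans[0].n_timepoints
    hit = (truth.true_peak_delay_trs == truth.est_peak_delay_trs).mean()
    print(f"simulated {n_scans} scans of {n_t} TRs x {cfg.n_voxels} voxels")
    print(f"extracted {analysis.responses.shape[0]} stimulus-event responses")
    print(f"HRF peak delay recovered exactly for {hit:.0%} of voxels "
          f"(all within +/-1 TR: {(abs(truth.true_peak_delay_trs - truth.est_peak_delay_trs) <= 1).all()})")
    print(f"top-activation voxel set: {len(analysis.top_voxels.indices)} voxels")


if __name__ == "__main__":
    main()
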