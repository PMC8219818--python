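"""End-to-end simulated-study pipeline.

Chains the stages on synthetic data: factorial design -> per-scan
schedules -> BOLD simulation -> detrend + blank-baseline z-scoring ->
per-voxel HRF estimation (single-condition rank-1 FIR GLM) -> event
response extraction -> condition-wise GLM contrasts, MVPA decoding and
voxel-wise encoding (responsiveness, selectivity, LORO validation),
aggregated across simulated subjects.  Everything is reproducible from
the config seed; permutation counts of zero skip inference while still
producing the estimates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, encoding, extract, glm, mvpa, schedule, simulate
from .stats import permutation_pvalue


@dataclass(frozen=True)
class PipelineConfig:
    """Study-level simulation and analysis parameters."""

    n_subjects: int = 14
    n_voxels: int = 40
    scenario: str = "scale_negative"
    seed: int = 0
    n_scans: int = 5
    tr_s: float = 0.7
    fir_length: int = 20
    noise_sd: float = 1.0
    ridge_penalty: float = 1.0
    k_top_voxels: int = 50
    top_fraction: float = 0.3
    n_perm_glm: int = 0
    n_perm_mvpa: int = 0
    n_perm_encoding: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if self.n_voxels < 1:
            problems.append("n_voxels must be >= 1")
        if self.n_scans < 2:
            problems.append("n_scans must be >= 2 (leave-one-run-out)")
        if self.scenario not in ("null", "scale_negative", "heterogeneous"):
            problems.append(f"unknown scenario {self.scenario!r}")
        for key in ("n_perm_glm", "n_perm_mvpa", "n_perm_encoding"):
            if getattr(self, key) < 0:
                problems.append(f"{key} must be >= 0")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


@dataclass
class SubjectData:
    """Raw synthetic data for one subject."""

    subject: int
    schedules: list
    scans: list  # BoldScan per run
    ground_truths: list


@dataclass
class SubjectAnalysis:
    """Extracted quantities for one subject, ready for the analyses."""

    subject: int
    responses: np.ndarray  # (n_events, n_voxels) at per-voxel delays
    events: pd.DataFrame  # scan, scale_level, misscale_direction, image_id
    features: np.ndarray  # (n_events, 4) normalized
    peak_delays: np.ndarray  # (n_voxels,)
    top_voxels: extract.TopVoxelSet
    z_data: np.ndarray  # concatenated z series (n_voxels, total T)
    glm_events: pd.DataFrame  # scan, onset_tr, trial_type, scale_level, ...
    scan_slices: list


def build_design() -> tuple[pd.DataFrame, np.ndarray]:
    """The 120-image set with property levels and its feature matrix."""
    images = design.assign_property_levels(design.build_image_set())
    return images, design.feature_matrix(images)


def simulate_subject(
    images: pd.DataFrame, config: PipelineConfig, subject: int
) -> SubjectData:
    """Simulate one subject's scans with seeds derived from the config seed."""
    rng = np.random.default_rng([config.seed, subject])
    gts = simulate.make_ground_truths(
        config.n_voxels,
        config.scenario,
        seed=int(rng.integers(2**31)),
        noise_sd=config.noise_sd,
    )
    feat_by_image = pd.DataFrame(
        design.feature_matrix(images), index=images["image_id"]
    )
    schedules, scans = [], []
    for _ in range(config.n_scans):
        sched = schedule.schedule_scan(images, seed=int(rng.integers(2**31)))
        feats = feat_by_image.loc[
            sched.stimulus_trials["image_id"].to_numpy()
        ].to_numpy()
        scans.append(
            simulate.simulate_scan(
                sched,
                feats,
                gts,
                seed=int(rng.integers(2**31)),
                tr_s=config.tr_s,
                fir_length=config.fir_length,
            )
        )
        schedules.append(sched)
    return SubjectData(subject=subject, schedules=schedules, scans=scans,
                       ground_truths=gts)


def _stimulus_meta(sched, images: pd.DataFrame, scan_index: int) -> pd.DataFrame:
    stim = sched.stimulus_trials
    meta = images.set_index("image_id").loc[
        stim["image_id"].to_numpy(),
        ["scale_level", "misscale_direction", "manipulation"],
    ]
    meta = meta.reset_index()
    meta.insert(0, "scan", scan_index)
    return meta


def prepare_subject(
    data: SubjectData, images: pd.DataFrame, config: PipelineConfig
) -> SubjectAnalysis:
    """Detrend, z-score, estimate per-voxel HRF delays and extract responses."""
    zs_per_scan = [
        extract.zscore_blank_baseline(extract.detrend_linear(scan))
        for scan in data.scans
    ]
    # concatenated z series + GLM event table (all trials, incl. task)
    z_data = np.hstack([zs.z for zs in zs_per_scan])
    scan_slices, offset = [], 0
    glm_rows = []
    for s, zs in enumerate(zs_per_scan):
        n_t = zs.z.shape[1]
        scan_slices.append((offset, offset + n_t))
        offset += n_t
        trials = zs.schedule.trials
        onset_trs = np.round(
            trials["object_onset_s"].to_numpy() / config.tr_s
        ).astype(int)
        df = pd.DataFrame(
            {
                "scan": s,
                "onset_tr": onset_trs,
                "trial_type": trials["trial_type"].to_numpy(),
                "image_id": trials["image_id"].to_numpy(),
            }
        )
        glm_rows.append(df)
    glm_events = pd.concat(glm_rows, ignore_index=True)
    stim_mask = glm_events["trial_type"] == "stimulus"
    img_meta = images.set_index("image_id")
    glm_events.loc[stim_mask, "scale_level"] = img_meta.loc[
        glm_events.loc[stim_mask, "image_id"], "scale_level"
    ].to_numpy()
    glm_events.loc[stim_mask, "misscale_direction"] = img_meta.loc[
        glm_events.loc[stim_mask, "image_id"], "misscale_direction"
    ].to_numpy()

    _, delays = glm.fit_single_condition_hrf(
        z_data,
        glm_events.assign(condition="all"),
        scan_slices,
        fir_length=config.fir_length,
        tr_s=config.tr_s,
    )

    responses = np.vstack(
        [
            extract.extract_event_responses(zs, delays, onset="object")
            for zs in zs_per_scan
        ]
    )
    events = pd.concat(
        [
            _stimulus_meta(sched, images, s)
            for s, sched in enumerate(data.schedules)
        ],
        ignore_index=True,
    )
    feat_by_image = pd.DataFrame(
        design.feature_matrix(images), index=images["image_id"]
    )
    features = feat_by_image.loc[events["image_id"].to_numpy()].to_numpy()
    top = extract.select_top_voxels(zs_per_scan, k=config.k_top_voxels)
    return SubjectAnalysis(
        subject=data.subject,
        responses=responses,
        events=events,
        features=features,
        peak_delays=delays,
        top_voxels=top,
        z_data=z_data,
        glm_events=glm_events,
        scan_slices=scan_slices,
    )


def subject_glm_contrasts(
    analysis: SubjectAnalysis, config: PipelineConfig, mode: str
):
    """Observed voxel-mean R1-GLM contrast(s) for one subject."""
    ev = analysis.glm_events.copy()
    stim = ev["trial_type"] == "stimulus"
    labels = glm.condition_labels(ev.loc[stim], mode)
    ev["condition"] = glm.TASK_CONDITION
    ev.loc[stim, "condition"] = labels
    fits = glm.fit_r1_glm_fir(
        analysis.z_data, ev, analysis.scan_slices,
        fir_length=config.fir_length, tr_s=config.tr_s,
    )
    mean_betas = pd.concat([f.betas for f in fits], axis=1).mean(axis=1)
    return mean_betas, glm.condition_contrast(mean_betas, mode)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full simulated study and return (optionally write) results."""
    config.validate()
    images, _ = build_design()
    corr, pvals = design.check_property_independence(images)

    subjects = []
    for s in range(config.n_subjects):
        data = simulate_subject(images, config, s)
        subjects.append(prepare_subject(data, images, config))

    results: dict = {
        "config": asdict(config),
        "independence_corr": corr,
        "independence_p": pvals,
    }

    # --- GLM contrasts (pooled and split by mis-scaling direction)
    glm_rows = []
    for ana in subjects:
        _, pooled = subject_glm_contrasts(ana, config, "pooled_6level")
        _, split = subject_glm_contrasts(ana, config, "split_by_direction")
        glm_rows.append(
            {
                "subject": ana.subject,
                "pooled": pooled,
                "too_small": split["too_small"],
                "too_large": split["too_large"],
            }
        )
    results["glm_contrasts"] = pd.DataFrame(glm_rows)

    # --- MVPA on top-activation voxels
    mvpa_rows = []
    null_by_subject = []
    for ana in subjects:
        responses = ana.responses[:, ana.top_voxels.indices]
        levels = ana.events["scale_level"].to_numpy()
        scan_ids = ana.events["scan"].to_numpy()
        if config.n_perm_mvpa > 0:
            res = mvpa.mvpa_permutation_null(
                responses, levels, scan_ids,
                n_perm=config.n_perm_mvpa, seed=config.seed * 997 + ana.subject,
            )
            null_by_subject.append(res.null_mean_pcs)
            observed = res.observed
        else:
            observed = mvpa.run_mvpa(responses, levels, scan_ids)
        mvpa_rows.append(
            {"subject": ana.subject, "mean_pc": observed.mean_pc, **{
                f"pc_L{lev}": pc for lev, pc in observed.pairing_pcs.items()
            }}
        )
    mvpa_df = pd.DataFrame(mvpa_rows)
    results["mvpa"] = mvpa_df
    results["mvpa_group_mean_pc"] = float(mvpa_df["mean_pc"].mean())
    if null_by_subject:
        group_null = np.mean(null_by_subject, axis=0)
        results["mvpa_group_null"] = group_null
        results["mvpa_group_p"] = permutation_pvalue(
            results["mvpa_group_mean_pc"], group_null, tail="greater"
        )

    # --- Encoding model: weights, responsiveness, selectivity, validation
    weight_rows, cond_mean_rows = [], []
    resp_nulls, sel_nulls, sel_obs = [], [], []
    for ana in subjects:
        sub_seed = config.seed * 2003 + ana.subject
        fit = encoding.fit_encoding(
            ana.responses, ana.features, config.ridge_penalty
        )
        weight_rows.append(
            {"subject": ana.subject, **dict(zip(design.FEATURES, fit.weights.mean(axis=0)))}
        )
        sel_obs.append(
            encoding.selectivity_ratio(fit.weights, 0, config.top_fraction)
        )
        if config.n_perm_encoding > 0:
            resp = encoding.responsiveness_test(
                ana.responses, ana.features,
                n_perm=config.n_perm_encoding, seed=sub_seed,
                ridge_penalty=config.ridge_penalty,
            )
            resp_nulls.append(resp.null_means)
            sel = encoding.selectivity_permutation_test(
                ana.responses, ana.features, target_feature=0,
                top_fraction=config.top_fraction,
                n_perm=config.n_perm_encoding, seed=sub_seed + 1,
                ridge_penalty=config.ridge_penalty,
            )
            sel_nulls.append(sel.null_ratios)
        pred = encoding.predict_bold_loro(
            ana.responses, ana.features,
            ana.events["scan"].to_numpy(), config.ridge_penalty,
        )
        cm = encoding.condition_means(pred, ana.events)
        cond_mean_rows.append(cm.rename(ana.subject))

    weights_df = pd.DataFrame(weight_rows)
    results["encoding_weights"] = weights_df
    group_mean_w = weights_df[list(design.FEATURES)].mean(axis=0)
    results["encoding_group_mean_weights"] = group_mean_w
    results["selectivity_observed"] = float(np.mean(sel_obs))
    if resp_nulls:
        group_null_w = np.mean(resp_nulls, axis=0)  # (n_perm, 4)
        results["responsiveness_p"] = pd.Series(
            [
                permutation_pvalue(group_mean_w.iloc[f], group_null_w[:, f],
                                   tail="two_sided")
                for f in range(4)
            ],
            index=design.FEATURES,
        )
    if sel_nulls:
        group_null_sel = np.mean(sel_nulls, axis=0)
        results["selectivity_null"] = group_null_sel
        results["selectivity_p"] = permutation_pvalue(
            results["selectivity_observed"], group_null_sel, tail="two_sided"
        )

    cond_df = pd.DataFrame(cond_mean_rows)
    cond_df.index.name = "subject"
    results["prediction_condition_means"] = cond_df
    if config.n_subjects >= 2:
        results["prediction_ttests"] = encoding.prediction_group_ttests(cond_df)

    if outdir is not None:
        _write_results(results, Path(outdir))
    return results


def _write_results(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(results["config"], fh, indent=2)
    for key in (
        "independence_corr",
        "glm_contrasts",
        "mvpa",
        "encoding_weights",
        "prediction_condition_means",
    ):
        if key in results:
            results[key].to_csv(outdir / f"{key}.tsv", sep="\t")
    if "prediction_ttests" in results:
        results["prediction_ttests"].to_csv(
            outdir / "prediction_ttests.tsv", sep="\t", index=False
        )
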