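"""Trial scheduling for one ~10 minute scan.

A scan presents the 120 stimulus images plus 20 fixation-task trials in
ten blocks of 14 trials.  Blocks alternate between the two manipulations
(FOV-manipulation block first), each holding 12 of that manipulation's 60
images plus 2 task trials at random positions.  A trial shows the scene
alone for a uniformly drawn 2-3.5 s period, then the target object for
0.5 s, then a 0.5 s blank; task trials omit the object.  10 s blank
periods separate the blocks, with an extra 10 s blank at the start and
end of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MANIPULATIONS

N_BLOCKS = 10
TRIALS_PER_BLOCK = 14
STIM_PER_BLOCK = 12
TASK_PER_BLOCK = 2
N_TASK_TRIALS = N_BLOCKS * TASK_PER_BLOCK  # 20


@dataclass(frozen=True)
class TimingConfig:
    """Trial and block timing parameters (seconds)."""

    scene_period_min_s: float = 2.0
    scene_period_max_s: float = 3.5
    object_duration_s: float = 0.5
    post_object_blank_s: float = 0.5
    block_blank_s: float = 10.0
    leading_blank_s: float = 10.0
    trailing_blank_s: float = 10.0


@dataclass
class ScanSchedule:
    """Ordered trials and blank periods for one scan.

    Attributes
    ----------
    trials : pandas.DataFrame
        One row per trial with columns ``onset_s`` (scene onset),
        ``scene_period_s``, ``object_onset_s``, ``duration_s``,
        ``trial_type`` (``stimulus``/``task``), ``image_id`` (None for
        task trials), ``object_id`` and ``block_index``.
    blank_periods : list of (start_s, end_s)
    scan_duration_s : float
    seed : int
    """

    trials: pd.DataFrame
    blank_periods: list[tuple[float, float]]
    scan_duration_s: float
    seed: int
    timing: TimingConfig = field(default_factory=TimingConfig)

    @property
    def stimulus_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == "stimulus"]

    def to_events_table(self) -> pd.DataFrame:
        """Event-file style table (onset, duration, trial_type, image_id)."""
        t = self.trials
        return pd.DataFrame(
            {
                "onset_s": t["onset_s"],
                "duration_s": t["duration_s"],
                "trial_type": t["trial_type"],
                "image_id": t["image_id"],
                "block_index": t["block_index"],
            }
        )


def _order_without_repeats(
    image_ids: np.ndarray,
    object_ids: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Permutation of indices with no consecutive repeat of the same object.

    Rejection sampling: a valid order of 6 copies of each of 10 objects
    appears roughly once per ~150 shuffles, so the bound is generous."""
    n = len(image_ids)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        objs = object_ids[perm]
        if not np.any(objs[1:] == objs[:-1]):
            return perm
    raise RuntimeError("could not satisfy no-consecutive-object constraint")


def schedule_scan(
    images: pd.DataFrame,
    seed: int,
    timing: TimingConfig | None = None,
) -> ScanSchedule:
    """Randomize the 120 images into one scan's block structure.

    The presentation order is randomized within each manipulation set
    (no target object on consecutive trials) before splitting into
    blocks; blocks alternate manipulation starting with the scene-FOV
    manipulation.  Task trials reuse each object's fixed-FOV scene twice
    per scan, two per block at random positions.
    """
    if timing is None:
        timing = TimingConfig()
    if len(images) != 120:
        raise ValueError(f"expected the 120-image set, got {len(images)} rows")
    rng = np.random.default_rng(seed)

    orders = {}
    for manip in MANIPULATIONS:
        sub = images[images["manipulation"] == manip].reset_index(drop=True)
        perm = _order_without_repeats(
            sub["image_id"].to_numpy(), sub["object_id"].to_numpy(), rng
        )
        orders[manip] = sub.iloc[perm].reset_index(drop=True)

    # 20 task trials: each object's fixed-FOV scene presented twice
    object_ids = images["object_id"].unique()
    task_objects = rng.permutation(np.repeat(object_ids, 2))

    rows = []
    blanks = [(0.0, timing.leading_blank_s)]
    t = timing.leading_blank_s
    cursor = {m: 0 for m in MANIPULATIONS}
    task_cursor = 0
    for block in range(N_BLOCKS):
        manip = "scene_fov" if block % 2 == 0 else "retinal_size"
        stim = orders[manip].iloc[
            cursor[manip] : cursor[manip] + STIM_PER_BLOCK
        ]
        cursor[manip] += STIM_PER_BLOCK
        task_pos = set(rng.choice(TRIALS_PER_BLOCK, TASK_PER_BLOCK, replace=False))
        stim_iter = iter(stim.itertuples())
        for pos in range(TRIALS_PER_BLOCK):
            scene_period = rng.uniform(
                timing.scene_period_min_s, timing.scene_period_max_s
            )
            duration = (
                scene_period + timing.object_duration_s + timing.post_object_blank_s
            )
            if pos in task_pos:
                trial_type, image_id = "task", None
                object_id = task_objects[task_cursor]
                task_cursor += 1
            else:
                img = next(stim_iter)
                trial_type, image_id, object_id = (
                    "stimulus",
                    img.image_id,
                    img.object_id,
                )
            rows.append(
                {
                    "onset_s": t,
                    "scene_period_s": scene_period,
                    "object_onset_s": t + scene_period,
                    "duration_s": duration,
                    "trial_type": trial_type,
                    "image_id": image_id,
                    "object_id": object_id,
                    "block_index": block,
                }
            )
            t += duration
        end_blank = (
            timing.trailing_blank_s if block == N_BLOCKS - 1 else timing.block_blank_s
        )
        blanks.append((t, t + end_blank))
        t += end_blank

    trials = pd.DataFrame(rows)
    return ScanSchedule(
        trials=trials,
        blank_periods=blanks,
        scan_duration_s=t,
        seed=seed,
        timing=timing,
    )


def schedule_session(
    images: pd.DataFrame,
    n_scans: int = 5,
    seed: int = 0,
    timing: TimingConfig | None = None,
) -> list[ScanSchedule]:
    """Independent schedules for the session's scans (sub-seeds by counter)."""
    return [
        schedule_scan(images, seed=int(seed) * 1000 + i, timing=timing)
        for i in range(n_scans)
    ]
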