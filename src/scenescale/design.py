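"""Factorial stimulus design and object-property levels.

The experiment presents 10 target objects embedded in scenes, each at six
object-scene scale-consistency levels (level 1 = normal scale, level 6 =
mis-scaled by a factor of 4), under two manipulations:

* ``retinal_size`` — the scene is fixed and the object's retinal size is
  scaled by the level's factor;
* ``scene_fov`` — the object's retinal size is fixed and the scene
  field-of-view (FOV) is scaled instead, changing the object's size
  *relative* to its surroundings.

Half of the objects (small real-world items) are mis-scaled to be too
large, the other half (large real-world items) to be too small.  This
yields 10 objects x 2 manipulations x 6 levels = 120 images, 20 per scale
level and 12 per object.

Each image additionally carries ordinal levels for three nuisance
properties — object retinal size, real-world object size, and scene FOV —
derived from raw (degrees / inches) values by quantile binning.  The
factorial structure makes the scale-consistency level exactly orthogonal
to any object-constant property (e.g. real-world size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Fixed feature-column order used everywhere downstream.
FEATURES = ("scale_consistency", "retinal_size", "real_world_size", "fov")

MANIPULATIONS = ("retinal_size", "scene_fov")

N_OBJECTS = 10
N_LEVELS = 6
N_IMAGES = N_OBJECTS * len(MANIPULATIONS) * N_LEVELS  # 120


@dataclass(frozen=True)
class ObjectSpec:
    """One target object of the factorial design.

    Parameters
    ----------
    object_id : str
        Unique name of the object.
    real_world_size_in : float
        Real-world size in inches (diagonal through the 3D bounding volume).
    misscale_direction : str
        ``"too_large"`` if the object grows relative to the scene when
        mis-scaled (small real-world items), ``"too_small"`` if it shrinks
        (large real-world items).
    base_retinal_deg : float
        Retinal diagonal of the object (degrees of visual angle) at the
        normal scale level.
    base_fov_deg : float
        Field-of-view of the object's scene (degrees) at the normal level.
    """

    object_id: str
    real_world_size_in: float
    misscale_direction: str
    base_retinal_deg: float
    base_fov_deg: float

    def __post_init__(self) -> None:
        if self.misscale_direction not in ("too_small", "too_large"):
            raise ValueError(
                f"misscale_direction must be 'too_small' or 'too_large', "
                f"got {self.misscale_direction!r}"
            )


def default_objects() -> list[ObjectSpec]:
    """The ten household/street objects of the study design.

    Real-world sizes are plausible per-object constants (inches, 3D
    diagonal); base retinal sizes and scene FOVs are chosen so that at the
    normal level small objects occupy ~1 degree and large objects ~3
    degrees of the 10 x 5.84 degree image, with slightly irregular values
    to avoid rank ties across objects.
    """
    small = [  # mis-scaled to be too large
        ObjectSpec("toothbrush", 9.0, "too_large", 0.82, 22.0),
        ObjectSpec("teacup", 6.0, "too_large", 0.93, 24.0),
        ObjectSpec("computer_mouse", 5.0, "too_large", 0.87, 20.0),
        ObjectSpec("bedside_lamp", 22.0, "too_large", 1.43, 25.0),
        ObjectSpec("frying_pan", 17.0, "too_large", 1.31, 23.0),
    ]
    large = [  # mis-scaled to be too small
        ObjectSpec("sofa", 96.0, "too_small", 2.69, 28.0),
        ObjectSpec("car", 175.0, "too_small", 2.97, 33.0),
        ObjectSpec("bus_shelter", 130.0, "too_small", 3.23, 35.0),
        ObjectSpec("playground_slide", 110.0, "too_small", 2.84, 31.0),
        ObjectSpec("pool_table", 115.0, "too_small", 3.11, 27.0),
    ]
    return small + large


def make_scale_factors() -> tuple[float, ...]:
    """Six linearly spaced mis-scaling factors from 1 (normal) to 4."""
    return tuple(np.round(np.linspace(1.0, 4.0, N_LEVELS), 10))


def build_image_set(objects: list[ObjectSpec] | None = None) -> pd.DataFrame:
    """Construct the 120-image factorial stimulus set.

    Parameters
    ----------
    objects : list of ObjectSpec, optional
        Exactly 10 objects, 5 per mis-scaling direction.  Defaults to
        :func:`default_objects`.

    Returns
    -------
    pandas.DataFrame
        One row per image with columns ``image_id``, ``object_id``,
        ``manipulation``, ``scale_level``, ``scale_factor``,
        ``misscale_direction`` and the raw property values
        ``retinal_deg``, ``fov_deg``, ``real_world_in``.
    """
    if objects is None:
        objects = default_objects()
    if len(objects) != N_OBJECTS:
        raise ValueError(f"expected {N_OBJECTS} objects, got {len(objects)}")
    n_per_dir = {"too_small": 0, "too_large": 0}
    for obj in objects:
        n_per_dir[obj.misscale_direction] += 1
    if n_per_dir["too_small"] != 5 or n_per_dir["too_large"] != 5:
        raise ValueError(
            f"expected 5 objects per mis-scaling direction, got {n_per_dir}"
        )

    factors = make_scale_factors()
    rows = []
    for obj in objects:
        grow = obj.misscale_direction == "too_large"
        for manip in MANIPULATIONS:
            for level, factor in enumerate(factors, start=1):
                if manip == "retinal_size":
                    # fixed scene, object retinal size scaled
                    retinal = obj.base_retinal_deg * (factor if grow else 1 / factor)
                    fov = obj.base_fov_deg
                else:
                    # fixed object retinal size, scene FOV scaled; widening
                    # the FOV shrinks the surroundings, so the object looks
                    # relatively larger
                    retinal = obj.base_retinal_deg
                    fov = obj.base_fov_deg * (factor if grow else 1 / factor)
                rows.append(
                    {
                        "image_id": f"{obj.object_id}_{manip}_L{level}",
                        "object_id": obj.object_id,
                        "manipulation": manip,
                        "scale_level": level,
                        "scale_factor": factor,
                        "misscale_direction": obj.misscale_direction,
                        "retinal_deg": retinal,
                        "fov_deg": fov,
                        "real_world_in": obj.real_world_size_in,
                    }
                )
    images = pd.DataFrame(rows)
    assert len(images) == N_IMAGES
    return images


@dataclass(frozen=True)
class BinningConfig:
    """Number of ordinal levels per binned property."""

    retinal_size_levels: int = 5
    real_world_size_levels: int = 5
    fov_levels: int = 4


def quantile_levels(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Assign 1..n_levels ordinal levels by rank quantiles (midranks for ties).

    Tied raw values always receive the same level; the rule is invariant
    to any monotone transform of ``values``.
    """
    values = np.asarray(values, dtype=float)
    if np.all(values == values[0]):
        raise ValueError("cannot bin a constant property")
    ranks = stats.rankdata(values, method="average")
    levels = np.ceil(n_levels * ranks / len(values)).astype(int)
    return np.clip(levels, 1, n_levels)


def assign_property_levels(
    images: pd.DataFrame, binning: BinningConfig | None = None
) -> pd.DataFrame:
    """Attach the four ordinal property levels to every image.

    ``level_scale_consistency`` is the scale level itself; the three
    nuisance properties are binned from their raw values across the full
    image set.
    """
    if binning is None:
        binning = BinningConfig()
    out = images.copy()
    out["level_scale_consistency"] = out["scale_level"].to_numpy()
    out["level_retinal_size"] = quantile_levels(
        out["retinal_deg"].to_numpy(), binning.retinal_size_levels
    )
    out["level_real_world_size"] = quantile_levels(
        out["real_world_in"].to_numpy(), binning.real_world_size_levels
    )
    out["level_fov"] = quantile_levels(
        out["fov_deg"].to_numpy(), binning.fov_levels
    )
    return out


LEVEL_COLUMNS = {
    "scale_consistency": "level_scale_consistency",
    "retinal_size": "level_retinal_size",
    "real_world_size": "level_real_world_size",
    "fov": "level_fov",
}


def normalize_features(event_levels: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Normalize property levels column-wise to [-1, 1].

    Each column is centered on its mean and divided by its maximum
    absolute deviation, so a uniform 1..6 column maps to
    (-1, -0.6, -0.2, 0.2, 0.6, 1).
    """
    x = np.asarray(event_levels, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    centered = x - x.mean(axis=0)
    max_abs = np.abs(centered).max(axis=0)
    if np.any(max_abs == 0):
        bad = np.flatnonzero(max_abs == 0).tolist()
        raise ValueError(f"constant feature column(s) cannot be normalized: {bad}")
    return centered / max_abs


def feature_matrix(images_with_levels: pd.DataFrame) -> np.ndarray:
    """Normalized (n_images x 4) feature matrix in :data:`FEATURES` order."""
    levels = images_with_levels[[LEVEL_COLUMNS[f] for f in FEATURES]]
    return normalize_features(levels.to_numpy())


def check_property_independence(
    images_with_levels: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations among the four property levels.

    Returns
    -------
    (corr, pvals) : pair of 4x4 DataFrames
        Symmetric matrices indexed by feature name; the diagonal of
        ``corr`` is 1.  Ties are handled by midranks.  On the full
        factorial design the correlation between scale consistency and
        any object-constant property (real-world size) is exactly 0.
    """
    levels = images_with_levels[[LEVEL_COLUMNS[f] for f in FEATURES]].to_numpy()
    rho, p = stats.spearmanr(levels)
    corr = pd.DataFrame(rho, index=FEATURES, columns=FEATURES)
    pvals = pd.DataFrame(p, index=FEATURES, columns=FEATURES)
    return corr, pvals


def aggregate_perceived_ratings(ratings: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Aggregate per-subject scale-consistency ratings per image.

    Parameters
    ----------
    ratings : array (n_images, n_raters)
        Integer ratings coded 0 (extremely consistent) to 5 (extremely
        inconsistent).

    Returns
    -------
    ndarray of int
        Per-image mean rating rounded half-up to the nearest whole number.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    if r.size == 0:
        raise ValueError("at least one rating per image is required")
    if np.any((r < 0) | (r > 5)) or np.any(r != np.round(r)):
        raise ValueError("ratings must be integers in 0..5")
    means = r.mean(axis=1)
    return np.floor(means + 0.5).astype(int)  # round half-up
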