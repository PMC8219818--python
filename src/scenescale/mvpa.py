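"""Binary normal-vs-mis-scaled decoding with leave-one-run-out CV.

For each of the five pairings (normal scale level 1 vs one mis-scaled
level, in turn) a linear support vector machine is trained on the
top-activation voxels' event responses from four scans and tested on
the held-out fifth, each scan held out once.  Percent correct (PC) is
averaged over folds, then over the five pairings.  Chance is 50% since
classes are balanced (20 normal vs 20 mis-scaled events per scan); the
permutation null randomizes only the training labels, leaving test
labels intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .stats import permutation_pvalue

NORMAL_LEVEL = 1
MIS_LEVELS = (2, 3, 4, 5, 6)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize features using training-fold statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def run_loro_pairing(
    event_responses: np.ndarray,
    levels: np.ndarray,
    scan_ids: np.ndarray,
    pairing_level: int,
    C: float = 1.0,
    standardize: bool = True,
    shuffle_train_rng: np.random.Generator | None = None,
) -> float:
    """Percent correct for one pairing (level 1 vs ``pairing_level``).

    Class 1 is the normal scale level, class 0 the mis-scaled level.
    Ties on the decision boundary resolve toward class 0.  Passing
    ``shuffle_train_rng`` randomizes the training labels of every fold
    (the permutation null); test labels stay intact.
    """
    if pairing_level not in MIS_LEVELS:
        raise ValueError(f"pairing level must be one of {MIS_LEVELS}")
    levels = np.asarray(levels)
    scan_ids = np.asarray(scan_ids)
    responses = np.asarray(event_responses, dtype=float)
    mask = (levels == NORMAL_LEVEL) | (levels == pairing_level)
    X = responses[mask]
    y = (levels[mask] == NORMAL_LEVEL).astype(int)
    scans = scan_ids[mask]
    unique_scans = np.unique(scans)
    if len(unique_scans) < 2:
        raise ValueError("need at least 2 scans for leave-one-run-out CV")
    for s in unique_scans:
        counts = np.bincount(y[scans == s], minlength=2)
        if counts[0] != counts[1]:
            raise ValueError(
                f"unbalanced classes in scan {s}: {counts[0]} vs {counts[1]}"
            )

    fold_pcs = []
    for s in unique_scans:
        test = scans == s
        X_tr, X_te = X[~test], X[test]
        y_tr, y_te = y[~test], y[test]
        if shuffle_train_rng is not None:
            y_tr = shuffle_train_rng.permutation(y_tr)
        if standardize:
            X_tr, X_te = _standardize(X_tr, X_te)
        if len(np.unique(y_tr)) < 2:  # degenerate shuffled fold
            pred = np.zeros(len(y_te), dtype=int)
        else:
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_tr, y_tr)
            pred = (clf.decision_function(X_te) > 0).astype(int)
        fold_pcs.append(100.0 * np.mean(pred == y_te))
    return float(np.mean(fold_pcs))


@dataclass
class MVPAResult:
    """Per-pairing and mean percent-correct values."""

    pairing_pcs: dict[int, float]
    mean_pc: float


def run_mvpa(
    event_responses: np.ndarray,
    levels: np.ndarray,
    scan_ids: np.ndarray,
    C: float = 1.0,
    standardize: bool = True,
    shuffle_train_rng: np.random.Generator | None = None,
) -> MVPAResult:
    """Mean PC across the five normal-vs-mis-scaled pairings."""
    pcs = {
        lev: run_loro_pairing(
            event_responses,
            levels,
            scan_ids,
            lev,
            C=C,
            standardize=standardize,
            shuffle_train_rng=shuffle_train_rng,
        )
        for lev in MIS_LEVELS
    }
    return MVPAResult(pairing_pcs=pcs, mean_pc=float(np.mean(list(pcs.values()))))


@dataclass
class MVPANullResult:
    observed: MVPAResult
    null_mean_pcs: np.ndarray
    p_value: float


def mvpa_permutation_null(
    event_responses: np.ndarray,
    levels: np.ndarray,
    scan_ids: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    standardize: bool = True,
) -> MVPANullResult:
    """Training-label permutation null of the mean PC.

    Each permutation re-runs the identical LORO pipeline with training
    labels randomized (per-permutation rng derived from the master seed
    by counter); p is the proportion of null mean PCs at or above the
    observed mean PC.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = run_mvpa(
        event_responses, levels, scan_ids, C=C, standardize=standardize
    )
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        nulls[i] = run_mvpa(
            event_responses,
            levels,
            scan_ids,
            C=C,
            standardize=standardize,
            shuffle_train_rng=rng,
        ).mean_pc
    p = permutation_pvalue(observed.mean_pc, nulls, tail="greater")
    return MVPANullResult(observed=observed, null_mean_pcs=nulls, p_value=p)
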