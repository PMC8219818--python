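"""Shared inferential machinery.

Empirical permutation p-values use the plain proportion of null values
at or beyond the observed statistic, with no +1 smoothing, so p = 0 is
possible when the observed value beats every permutation (the +1/(n+1)
convention would be positively biased relative to this choice).
Two-sided p-values double the smaller tail, capped at 1.  Multiple
comparisons use Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def permutation_pvalue(
    observed: float, null_values: np.ndarray, tail: str = "greater"
) -> float:
    """Empirical p-value of ``observed`` against a permutation null.

    ``tail="greater"`` gives the proportion of null values >= observed,
    ``"less"`` the proportion <= observed, and ``"two_sided"`` twice the
    smaller of the two, capped at 1.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    ge = float(np.mean(null >= observed))
    le = float(np.mean(null <= observed))
    if tail == "greater":
        return ge
    if tail == "less":
        return le
    if tail == "two_sided":
        return min(1.0, 2.0 * min(ge, le))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class FDRResult:
    raw: np.ndarray
    adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR adjustment (adjusted p capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return FDRResult(raw=p, adjusted=adjusted, rejected=rejected, alpha=alpha)


def paired_t_onetailed(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """One-tailed paired t-test of mean(a - b) > 0.

    Returns (t, df, p) with df = n - 1.  Zero-variance differences give
    a flagged infinite statistic (t = +/-inf, p = 0 or 1) rather than an
    exception; identical vectors give t = 0, p = 0.5.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 0.5
        t = np.inf if mean > 0 else -np.inf
        return float(t), df, 0.0 if mean > 0 else 1.0
    t = mean / (sd / np.sqrt(n))
    p = float(sps.t.sf(t, df))
    return float(t), df, p
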