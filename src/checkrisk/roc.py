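"""Rank-based ROC/AUC computation and DeLong inference.

The AUC is computed as the tie-corrected Mann-Whitney probability: over all
case-control pairs, the fraction in which the case outscores the control, ties
counting one half.  Standard errors and confidence intervals come from
DeLong's structural-components (placement-value) estimator; paired AUC
comparisons on the same participants use the DeLong covariance of the two
placement vectors.  A degenerate closed form, ``(Se + Sp) / 2``, gives the AUC
of a rater who issues only a binary prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AucResult",
    "UndefinedAUCError",
    "auc_rank",
    "auc_binary_rater",
    "auc_delong",
    "auc_delong_paired",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined (an outcome class is empty)."""


@dataclass(frozen=True)
class AucResult:
    auc: float
    standard_error: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int
    level: float = 0.95


def _split(scores, outcomes):
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have the same length")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise UndefinedAUCError("need at least one case and one control")
    return cases, controls


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values via midranks (handles ties at 0.5).

    ``v10[i]`` = fraction of controls the i-th case outscores;
    ``v01[j]`` = fraction of cases the j-th control is outscored by.
    """
    m, n = len(cases), len(controls)
    pooled = np.concatenate([cases, controls])
    mid = stats.rankdata(pooled, method="average")
    rank_cases = stats.rankdata(cases, method="average")
    rank_controls = stats.rankdata(controls, method="average")
    v10 = (mid[:m] - rank_cases) / n
    v01 = 1.0 - (mid[m:] - rank_controls) / m
    auc = float(v10.mean())
    return v10, v01, auc


def auc_rank(scores, outcomes) -> float:
    """Tie-corrected Mann-Whitney AUC of ``scores`` against binary ``outcomes``."""
    cases, controls = _split(scores, outcomes)
    _, _, auc = _placements(cases, controls)
    return auc


def auc_binary_rater(tp: int, fp: int, fn: int, tn: int) -> float:
    """AUC of a binary (yes/no) rater: ``(Se + Sp) / 2``.

    Equivalent to the rank AUC of the 0/1 prediction expanded to participant
    level, and the closed form used to score clinician predictions recorded
    only as confusion counts.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedAUCError("empty case or control margin")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return (se + sp) / 2.0


def auc_delong(scores, outcomes, level: float = 0.95) -> AucResult:
    """AUC with DeLong standard error and Wald confidence interval.

    The variance is ``var(v10)/m + var(v01)/n`` from the placement values; the
    interval is symmetric on the AUC scale, truncated to [0, 1].  With perfect
    separation every placement is identical, the variance is zero, and the
    interval collapses to a point (a warning is emitted).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    cases, controls = _split(scores, outcomes)
    if len(cases) < 2 or len(controls) < 2:
        raise UndefinedAUCError("DeLong inference needs >=2 cases and >=2 controls")
    v10, v01, auc = _placements(cases, controls)
    var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
    se = float(np.sqrt(var))
    if se == 0.0:
        warnings.warn("zero DeLong variance (degenerate AUC); CI collapses to a point")
    z = stats.norm.ppf(0.5 + level / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return AucResult(auc, se, lo, hi, len(cases), len(controls), level)


def auc_delong_paired(scores_a, scores_b, outcomes) -> tuple[float, float]:
    """DeLong test for the difference of two AUCs measured on the same participants.

    Returns ``(z, p)`` with a two-sided normal p-value.  When the variance of
    the AUC difference is zero (e.g. the two scores are identical or related
    by a strictly monotone transform), the result is the exact tie ``(0, 1)``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must be aligned to the same participants")
    outcomes = np.asarray(outcomes)
    mask = outcomes == 1
    va10, va01, auc_a = _placements(scores_a[mask], scores_a[~mask])
    vb10, vb01, auc_b = _placements(scores_b[mask], scores_b[~mask])
    m, n = mask.sum(), (~mask).sum()
    if m < 2 or n < 2:
        raise UndefinedAUCError("DeLong inference needs >=2 cases and >=2 controls")
    s10 = np.cov(va10, vb10, ddof=1)
    s01 = np.cov(va01, vb01, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var < 1e-12 / (m + n):  # exact tie up to floating error
        return 0.0, 1.0
    z = float((auc_a - auc_b) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p
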