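"""Threshold sweep, chance-corrected quality indices, and concentration of risk.

A positive test at cutoff ``k`` means score >= k.  For each cutoff the module
reports the full screening-metric set: sensitivity, specificity, Youden's J,
predictive values, raw efficiency (accuracy), the odds ratio of the 2x2, and
the chance-corrected quality indices

    k(1)   = (NPV - (1 - P)) / P          quality of sensitivity,
    k(0)   = (PPV - P) / (1 - P)          quality of specificity,
    k(0.5) = harmonic mean of k(1), k(0)  quality of efficiency,

where P is the outcome prevalence.  These rescale the predictive values onto a
kappa-like scale: 1 for a perfect test, 0 for a test independent of outcome.
The concentration-of-risk curve reports, for each top fraction q of scores,
what fraction of all observed events falls inside it; with integer scores the
realized flagged fraction at a threshold rarely equals q exactly, so entire
score levels are flagged and the realized fraction is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutpointMetrics",
    "CaptureCurve",
    "UndefinedMetricError",
    "confusion_at_cut",
    "cutpoint_metrics",
    "cutpoint_table",
    "cutpoint_frame",
    "optimal_cut",
    "concentration_of_risk",
]


class UndefinedMetricError(ValueError):
    """A screening statistic is undefined for the given confusion matrix."""


@dataclass(frozen=True)
class CutpointMetrics:
    """All screening statistics derived from one 2x2 confusion matrix."""

    cutoff: int
    tp: int
    fp: int
    fn: int
    tn: int
    prevalence: float
    positivity: float
    sensitivity: float
    specificity: float
    youden_j: float
    ppv: float  # NaN when no participant tests positive
    npv: float
    efficiency: float
    k1: float
    k0: float
    k05: float
    odds_ratio: float
    or_ci: tuple[float, float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at_cut(scores, outcomes, cutoff: int) -> tuple[int, int, int, int]:
    """Confusion counts (tp, fp, fn, tn) with positive test = score >= cutoff."""
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes)
    if len(scores) == 0:
        raise ValueError("empty cohort")
    pos = scores >= cutoff
    case = outcomes == 1
    tp = int(np.sum(pos & case))
    fp = int(np.sum(pos & ~case))
    fn = int(np.sum(~pos & case))
    tn = int(np.sum(~pos & ~case))
    return tp, fp, fn, tn


def cutpoint_metrics(tp: int, fp: int, fn: int, tn: int, cutoff: int = 0) -> CutpointMetrics:
    """Derive every screening statistic from the four confusion counts."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n = tp + fp + fn + tn
    n_case = tp + fn
    n_control = fp + tn
    if n_case == 0:
        raise UndefinedMetricError("sensitivity undefined: no cases")
    if n_control == 0:
        raise UndefinedMetricError("specificity undefined: no controls")
    p = n_case / n
    q = (tp + fp) / n
    se = tp / n_case
    sp = tn / n_control
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    j = se + sp - 1.0
    eff = (tp + tn) / n
    # chance-corrected predictive values
    k1 = (npv - (1.0 - p)) / p if not np.isnan(npv) else float("nan")
    k0 = (ppv - p) / (1.0 - p) if not np.isnan(ppv) else float("nan")
    if np.isnan(k1) or np.isnan(k0):
        k05 = float("nan")
    elif k1 + k0 == 0:
        k05 = 0.0
    else:
        k05 = 2.0 * k1 * k0 / (k1 + k0)
    if fp > 0 and fn > 0:
        odds_ratio = (tp * tn) / (fp * fn)
    else:
        odds_ratio = float("inf") if tp * tn > 0 else float("nan")
    if min(tp, fp, fn, tn) > 0:
        se_log = np.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        lo = float(np.exp(np.log(odds_ratio) - 1.959963984540054 * se_log))
        hi = float(np.exp(np.log(odds_ratio) + 1.959963984540054 * se_log))
    else:
        lo = hi = float("nan")
    return CutpointMetrics(
        cutoff=int(cutoff), tp=tp, fp=fp, fn=fn, tn=tn,
        prevalence=p, positivity=q, sensitivity=se, specificity=sp,
        youden_j=j, ppv=ppv, npv=npv, efficiency=eff,
        k1=k1, k0=k0, k05=k05, odds_ratio=odds_ratio, or_ci=(lo, hi),
    )


def cutpoint_table(scores, outcomes, cutoffs: Sequence[int]) -> list[CutpointMetrics]:
    """Full threshold sweep: one CutpointMetrics per cutoff, sorted by cutoff."""
    return [
        cutpoint_metrics(*confusion_at_cut(scores, outcomes, c), cutoff=c)
        for c in sorted(cutoffs)
    ]


def cutpoint_frame(table: Sequence[CutpointMetrics]) -> pd.DataFrame:
    """Tabular (DataFrame) form of a cut-point sweep, one row per cutoff."""
    rows = []
    for m in table:
        d = asdict(m)
        lo, hi = d.pop("or_ci")
        d["or_ci_lower"], d["or_ci_upper"] = lo, hi
        rows.append(d)
    return pd.DataFrame(rows)


def optimal_cut(table: Sequence[CutpointMetrics]) -> int:
    """Cutoff maximizing Youden's J; ties go to the lower cutoff (higher Se)."""
    if not table:
        raise ValueError("empty cut-point table")
    best = max(table, key=lambda m: (m.youden_j, -m.cutoff))
    return best.cutoff


@dataclass(frozen=True)
class CaptureCurve:
    """Concentration-of-risk curve: events captured within the top score fractions."""

    top_fractions: tuple[float, ...]
    thresholds: tuple[int, ...]
    flagged_fractions: tuple[float, ...]
    events_captured: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "top_fraction": self.top_fractions,
                "threshold": self.thresholds,
                "flagged_fraction": self.flagged_fractions,
                "events_captured_fraction": self.events_captured,
            }
        )


def concentration_of_risk(scores, outcomes, top_fractions: Sequence[float]) -> CaptureCurve:
    """Fraction of all events occurring among the top-q fraction of scores.

    For each requested fraction q the threshold is the smallest score level s
    such that flagging everyone with score >= s flags at most a q-fraction of
    the cohort; when no level flags that few (q smaller than the top level's
    mass), the smallest attainable flagged fraction above q is used.  Whole
    score levels are always flagged together, so the realized flagged fraction
    is reported next to the nominal q.
    """
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes)
    n = len(scores)
    total_events = int(np.sum(outcomes == 1))
    if total_events == 0:
        raise UndefinedMetricError("capture undefined: no events in cohort")
    for q in top_fractions:
        if not 0 < q <= 1:
            raise ValueError(f"top fractions must be in (0, 1], got {q}")
    levels = np.unique(scores)[::-1]  # descending
    tail_counts = np.array([(scores >= s).sum() for s in levels])
    tail_events = np.array([int(np.sum((scores >= s) & (outcomes == 1))) for s in levels])

    thresholds, flagged, captured = [], [], []
    for q in top_fractions:
        within = tail_counts <= q * n
        idx = int(np.max(np.nonzero(within)[0])) if within.any() else 0
        thresholds.append(int(levels[idx]))
        flagged.append(tail_counts[idx] / n)
        captured.append(tail_events[idx] / total_events)
    return CaptureCurve(
        tuple(float(q) for q in top_fractions),
        tuple(thresholds),
        tuple(float(f) for f in flagged),
        tuple(float(c) for c in captured),
    )
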