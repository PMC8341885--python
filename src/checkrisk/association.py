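"""Logistic calibration, Nagelkerke pseudo-R2, and contingency analysis.

The univariate logistic model ``logit P(event) = alpha + beta * score`` is the
calibration companion to the rank-based discrimination metrics: ``exp(beta)``
is the per-point odds ratio.  2x2 contingency tables yield risk ratios, odds
ratios, Wald intervals on the log scale (z = 1.96), and Pearson's chi-squared
test.  The risk-group table compares each score band against the lowest band,
the table convention of clinical risk-score reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .checklist import ChecklistDefinition, ScoredCohort, score_cohort
from .roc import AucResult, auc_delong

__all__ = [
    "LogisticFit",
    "ContingencyResult",
    "fit_logistic",
    "two_by_two",
    "risk_group_table",
    "subgroup_auc",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    slope_se: float
    odds_ratio: float
    or_ci: tuple[float, float]
    log_likelihood: float
    null_log_likelihood: float
    nagelkerke_r2: float
    n: int
    converged: bool


def fit_logistic(x, y, level: float = 0.95) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression of binary ``y`` on ``x``.

    Fit by iteratively reweighted least squares (Newton scoring) with Wald
    standard errors from the observed information matrix.  The per-unit odds
    ratio is ``exp(slope)`` with a Wald interval on the log scale.  Nagelkerke's
    pseudo-R2 rescales the Cox-Snell statistic to a [0, 1] range:

        R2_N = [1 - exp(2 (LL0 - LL1) / n)] / [1 - exp(2 LL0 / n)].

    Complete separation is reported via ``converged=False`` rather than an
    exception, since the coefficient path is still informative diagnostically.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not np.isfinite(x).all():
        raise ValueError("x must be finite")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all() or len(classes) < 2:
        raise ValueError("y must contain both outcome classes (0 and 1)")
    n = len(y)
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = model.fit(method="bfgs", maxiter=200, disp=False)
            converged = False
    intercept, slope = res.params
    slope_se = float(res.bse[1])
    ll1 = float(res.llf)
    ll0 = float(res.llnull)
    z = stats.norm.ppf(0.5 + level / 2)
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = float(cox_snell / max_r2) if max_r2 > 0 else 0.0
    nagelkerke = min(max(nagelkerke, 0.0), 1.0)
    return LogisticFit(
        intercept=float(intercept),
        slope=float(slope),
        slope_se=slope_se,
        odds_ratio=float(np.exp(slope)),
        or_ci=(float(np.exp(slope - z * slope_se)), float(np.exp(slope + z * slope_se))),
        log_likelihood=ll1,
        null_log_likelihood=ll0,
        nagelkerke_r2=nagelkerke,
        n=n,
        converged=converged,
    )


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 analysis of (a, b | c, d) = (exposed events, exposed non-events |
    unexposed events, unexposed non-events)."""

    a: int
    b: int
    c: int
    d: int
    rate_exposed: float
    rate_unexposed: float
    risk_ratio: float
    odds_ratio: float
    rr_ci: tuple[float, float]
    or_ci: tuple[float, float]
    chi_square: float
    p: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


def two_by_two(a: int, b: int, c: int, d: int, haldane: bool = False) -> ContingencyResult:
    """Risk ratio, odds ratio, Wald CIs, and Pearson chi-squared for a 2x2 table.

    ``a``/``b`` are events/non-events among the exposed, ``c``/``d`` among the
    unexposed.  CIs are Wald on the log scale, e.g. for the OR
    ``exp(log OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``.  With a zero cell the
    estimates are infinite/undefined unless ``haldane=True`` adds 0.5 to every
    cell.  The chi-squared test is uncorrected (1 df), computed on the raw
    counts regardless of the Haldane option.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("each exposure margin must be positive")
    rate_exp = a / (a + b)
    rate_unexp = c / (c + d)
    aa, bb, cc, dd = (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if haldane else (a, b, c, d)
    if min(aa, bb, cc, dd) == 0:
        or_ = (aa * dd) / (bb * cc) if bb * cc > 0 else (float("inf") if aa * dd > 0 else float("nan"))
        rr_num, rr_den = aa / (aa + bb), cc / (cc + dd)
        rr = rr_num / rr_den if rr_den > 0 else (float("inf") if rr_num > 0 else float("nan"))
        rr_ci = or_ci = (float("nan"), float("nan"))
    else:
        rr = (aa / (aa + bb)) / (cc / (cc + dd))
        or_ = (aa * dd) / (bb * cc)
        se_log_or = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        se_log_rr = np.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))
        or_ci = (float(np.exp(np.log(or_) - _Z95 * se_log_or)), float(np.exp(np.log(or_) + _Z95 * se_log_or)))
        rr_ci = (float(np.exp(np.log(rr) - _Z95 * se_log_rr)), float(np.exp(np.log(rr) + _Z95 * se_log_rr)))
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p = 0.0, 1.0
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        rate_exposed=rate_exp, rate_unexposed=rate_unexp,
        risk_ratio=float(rr), odds_ratio=float(or_),
        rr_ci=rr_ci, or_ci=or_ci,
        chi_square=float(chi2), p=float(p),
        corrected=haldane,
    )


def risk_group_table(scored: ScoredCohort) -> pd.DataFrame:
    """Per-band counts, rates, cumulative percentages, and RR/OR vs the lowest band.

    The reference category is always the lowest band; comparisons for a band
    are computed by ``two_by_two`` (events/non-events in the band vs the
    reference band).  Returns one row per band plus a ``Total`` row.
    """
    definition = scored.definition
    bands = list(definition.band_names)
    ranges = [
        f"{b.lower}+" if b.upper is None else f"{b.lower}-{b.upper}" for b in definition.bands
    ]
    n = len(scored)
    rows = []
    per_band = {}
    for name in bands:
        in_band = scored.bands == name
        events = int(np.sum(scored.outcomes[in_band] == 1))
        controls = int(np.sum(in_band)) - events
        per_band[name] = (events, controls)
    ref_events, ref_controls = per_band[bands[0]]
    if ref_events + ref_controls == 0:
        raise ValueError("reference (lowest) band is empty")
    cum = 0.0
    for name, rng in zip(bands, ranges):
        events, controls = per_band[name]
        total = events + controls
        cum += total / n
        row = {
            "band": name,
            "range": rng,
            "pct_of_sample": total / n,
            "cumulative_pct": cum,
            "controls": controls,
            "attempters": events,
            "total": total,
            "rate": events / total if total else float("nan"),
        }
        if name == bands[0]:
            row.update({"risk_ratio": 1.0, "odds_ratio": 1.0,
                        "or_ci_lower": float("nan"), "or_ci_upper": float("nan"),
                        "p": float("nan")})
        elif total == 0:
            row.update({k: float("nan") for k in
                        ("risk_ratio", "odds_ratio", "or_ci_lower", "or_ci_upper", "p")})
        else:
            res = two_by_two(events, controls, ref_events, ref_controls)
            row.update({
                "risk_ratio": res.risk_ratio,
                "odds_ratio": res.odds_ratio,
                "or_ci_lower": res.or_ci[0],
                "or_ci_upper": res.or_ci[1],
                "p": res.p,
            })
        rows.append(row)
    total_events = int(np.sum(scored.outcomes == 1))
    rows.append({
        "band": "Total", "range": "", "pct_of_sample": 1.0, "cumulative_pct": 1.0,
        "controls": n - total_events, "attempters": total_events, "total": n,
        "rate": total_events / n,
        "risk_ratio": float("nan"), "odds_ratio": float("nan"),
        "or_ci_lower": float("nan"), "or_ci_upper": float("nan"), "p": float("nan"),
    })
    return pd.DataFrame(rows)


def subgroup_auc(
    cohort: pd.DataFrame,
    definition: ChecklistDefinition,
    group_column: str,
) -> dict[str, AucResult | None]:
    """Score the cohort, then DeLong AUC within each level of ``group_column``.

    Groups lacking both outcome classes are reported as ``None`` (skipped)
    rather than failing the whole analysis.
    """
    if group_column not in cohort.columns:
        raise ValueError(f"group column {group_column!r} not in cohort")
    out: dict[str, AucResult | None] = {}
    for value, sub in cohort.groupby(group_column, sort=True):
        scored = score_cohort(sub.reset_index(drop=True), definition)
        try:
            out[str(value)] = auc_delong(scored.scores, scored.outcomes)
        except Exception:
            out[str(value)] = None
    return out
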