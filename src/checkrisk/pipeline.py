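"""End-to-end orchestration: validate and develop runs, report serialization.

``run_validate`` composes the evaluation battery — DeLong AUC, logistic
calibration, the risk-group table, the cut-point sweep, and the
concentration-of-risk curve — into a single JSON-serializable report with a
provenance block (seed, package version, input checksums).  ``run_develop``
wraps candidate ranking, forward selection, and weight doubling into a final
checklist definition plus a trace table.  "Count mode" rebuilds the report
quantities that are derivable from pre-tabulated band counts, for datasets
published only as count tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import fit_logistic, risk_group_table, subgroup_auc
from .checklist import (
    ChecklistDefinition,
    load_definition,
    load_default_definition,
    read_cohort,
    score_cohort,
)
from .development import (
    EvidenceRecord,
    SelectionParams,
    forward_select,
    rank_candidates,
    weight_doubling,
)
from .roc import auc_delong
from .signal_detection import (
    concentration_of_risk,
    cutpoint_frame,
    cutpoint_metrics,
    cutpoint_table,
    optimal_cut,
)
from .synthetic import FixtureSet

__all__ = ["RunConfig", "run_validate", "run_develop", "validate_counts", "round_report"]

DEFAULT_TOP_FRACTIONS = (0.01, 0.05, 0.15)


@dataclass(frozen=True)
class RunConfig:
    cohort_path: str | Path | None = None
    definition_path: str | Path | None = None
    seed: int = 0
    ci_level: float = 0.95
    rounding: str = "full"  # "full" | "paper"
    group_column: str | None = None
    top_fractions: tuple[float, ...] = DEFAULT_TOP_FRACTIONS

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.rounding not in ("full", "paper"):
            raise ValueError("rounding profile must be 'full' or 'paper'")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _provenance(config: RunConfig, inputs: dict[str, str | Path | None]) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "ci_level": config.ci_level,
        "rounding": config.rounding,
        "input_checksums": {
            name: _sha256(p) for name, p in inputs.items() if p is not None
        },
    }


def _paper_round(key: str, value: float) -> float:
    """The reporting rounding rules: rates to 1 dp (%), OR/RR to 1 dp, AUC and
    kappa-type indices to 2 dp."""
    if any(t in key for t in ("auc", "sensitivity", "specificity", "youden", "k1", "k0", "k05",
                              "ppv", "npv", "efficiency", "ci_")):
        return round(value, 2)
    if any(t in key for t in ("odds_ratio", "risk_ratio", "or_ci", "rr_ci")):
        return round(value, 1)
    if "rate" in key or "pct" in key or "fraction" in key or "prevalence" in key:
        return round(value, 3)
    return value


def round_report(obj, profile: str, _key: str = ""):
    """Apply the rounding profile recursively to a report structure."""
    if profile == "full":
        return obj
    if isinstance(obj, dict):
        return {k: round_report(v, profile, k) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_report(v, profile, _key) for v in obj]
    if isinstance(obj, float):
        return _paper_round(_key, obj)
    return obj


def _to_native(obj):
    """Convert numpy scalars (and containers of them) to JSON-native types."""
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _frame_records(df: pd.DataFrame) -> list[dict]:
    return _to_native(df.replace({np.nan: None}).to_dict(orient="records"))


def run_validate(config: RunConfig) -> dict:
    """Full validation run on a raw cohort: returns the report as a dict.

    Deterministic given the inputs; the report carries a provenance block with
    input checksums so every table is re-derivable from the stored cohort.
    """
    if config.cohort_path is None:
        raise ValueError("count-free validate run needs a cohort path")
    definition = (
        load_definition(config.definition_path)
        if config.definition_path
        else load_default_definition()
    )
    cohort = read_cohort(config.cohort_path, definition)
    scored = score_cohort(cohort, definition)
    if scored.outcomes.sum() == 0:
        raise ValueError(
            "cohort has zero events: AUC, logistic fit, risk ratios, and "
            "capture curve are all undefined"
        )

    auc = auc_delong(scored.scores, scored.outcomes, level=config.ci_level)
    logistic = fit_logistic(scored.scores, scored.outcomes, level=config.ci_level)
    groups = risk_group_table(scored)
    cutoffs = list(range(int(scored.scores.min()) + 1, int(scored.scores.max()) + 1))
    table = cutpoint_table(scored.scores, scored.outcomes, cutoffs)
    capture = concentration_of_risk(scored.scores, scored.outcomes, config.top_fractions)

    report = {
        "schema_version": 1,
        "provenance": _provenance(
            config, {"cohort": config.cohort_path, "definition": config.definition_path}
        ),
        "definition": {"name": definition.name, "version": definition.version,
                       "n_items": len(definition.items), "max_score": definition.max_score},
        "score_summary": scored.summary,
        "auc": {
            "auc": auc.auc, "standard_error": auc.standard_error,
            "ci_lower": auc.ci_lower, "ci_upper": auc.ci_upper,
            "n_cases": auc.n_cases, "n_controls": auc.n_controls,
        },
        "logistic": {
            "intercept": logistic.intercept, "slope": logistic.slope,
            "slope_se": logistic.slope_se, "odds_ratio": logistic.odds_ratio,
            "or_ci": list(logistic.or_ci), "nagelkerke_r2": logistic.nagelkerke_r2,
            "n": logistic.n, "converged": logistic.converged,
        },
        "risk_groups": _frame_records(groups),
        "cutpoints": _frame_records(cutpoint_frame(table)),
        "optimal_cut": optimal_cut(table),
        "capture_curve": _frame_records(capture.as_frame()),
    }
    if config.group_column:
        report["subgroup_auc"] = {
            k: (None if r is None else {"auc": r.auc, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper})
            for k, r in subgroup_auc(cohort, definition, config.group_column).items()
        }
    return round_report(_to_native(report), config.rounding)


def validate_counts(fixtures: FixtureSet, cohort: str = "pooled",
                    top_fractions: Sequence[float] = DEFAULT_TOP_FRACTIONS) -> dict:
    """Count-mode validation: recompute everything derivable from band counts.

    Band-boundary cut points (6 and 9 for the default bands) and the capture
    curve are exact; statistics needing within-band score detail are not
    reported in this mode.
    """
    scores, outcomes = fixtures.pseudo_scores(cohort)
    from .signal_detection import confusion_at_cut  # local to keep imports tidy

    cut_blocks = {}
    for cut in (6, 9):
        m = cutpoint_metrics(*confusion_at_cut(scores, outcomes, cut), cutoff=cut)
        cut_blocks[f"cut_{cut}"] = {
            "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "youden_j": m.youden_j, "ppv": m.ppv, "npv": m.npv,
            "k1": m.k1, "k0": m.k0, "k05": m.k05,
            "odds_ratio": m.odds_ratio, "or_ci": list(m.or_ci),
        }
    capture = concentration_of_risk(scores, outcomes, top_fractions)
    return _to_native({
        "mode": "counts",
        "cohort": cohort,
        "n": int(len(scores)),
        "cutpoints": cut_blocks,
        "capture_curve": _frame_records(capture.as_frame()),
    })


def run_develop(
    records: Sequence[EvidenceRecord],
    dev_cohorts: Sequence[pd.DataFrame],
    base_definition: ChecklistDefinition,
    params: SelectionParams | None = None,
) -> tuple[ChecklistDefinition, pd.DataFrame]:
    """Rank candidates, forward-select, apply weight doubling; return the final
    definition (retained items with final weights, bands from the base
    definition) and the trace table."""
    params = params or SelectionParams()
    order = rank_candidates(records)
    trace = forward_select(order, dev_cohorts, params)
    weights = weight_doubling(trace, params, dev_cohorts)
    base_items = {it.id: it for it in base_definition.items}
    from .checklist import ChecklistItem

    items = tuple(
        ChecklistItem(v, base_items[v].label if v in base_items else v, w)
        for v, w in weights.items()
    )
    definition = ChecklistDefinition(
        name=base_definition.name,
        version=base_definition.version + "+selected",
        items=items,
        bands=base_definition.bands,
        missing_policy=base_definition.missing_policy,
    )
    return definition, trace.as_frame()


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
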