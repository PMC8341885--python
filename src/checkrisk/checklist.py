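"""Weighted dichotomous-item checklists: definition, loading, scoring, risk bands.

A checklist is a list of present/absent items, each carrying a positive integer
weight; a participant's score is the sum of the weights of the items present.
Scores map onto contiguous, exhaustive risk bands (e.g. "Lowest risk" 0-2 up to
an unbounded top band).  Missing item responses contribute zero points -- the
convention used when the instrument is scored in routine clinical practice,
where an unassessed risk factor simply cannot add to the score.

Two definitions ship with the package: the default 23-item suicide-attempt risk
checklist (four double-weighted items, maximum score 27) and the classic
10-item SAD PERSONS scale (all items weight 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChecklistItem",
    "Band",
    "ChecklistDefinition",
    "SchemaError",
    "ScoredCohort",
    "load_definition",
    "load_default_definition",
    "load_sad_persons_definition",
    "score_participant",
    "assign_band",
    "score_cohort",
    "read_cohort",
    "write_cohort",
]

#: Accepted missing-data policies.  ``absent_as_zero`` is the only one defined:
#: a missing response contributes no points.
MISSING_POLICIES = ("absent_as_zero",)

#: Value used in cohort files to mark a missing item response.
MISSING_TOKEN = "NA"


class SchemaError(ValueError):
    """A checklist definition document violates the schema."""


@dataclass(frozen=True)
class ChecklistItem:
    id: str
    label: str
    weight: int


@dataclass(frozen=True)
class Band:
    """A contiguous score interval mapped to a named risk group.

    ``upper is None`` marks the unbounded top band.
    """

    name: str
    lower: int
    upper: int | None

    def contains(self, score: int) -> bool:
        return score >= self.lower and (self.upper is None or score <= self.upper)


@dataclass(frozen=True)
class ChecklistDefinition:
    name: str
    version: str
    items: tuple[ChecklistItem, ...]
    bands: tuple[Band, ...]
    missing_policy: str = "absent_as_zero"

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate item ids: {sorted(dupes)}")
        for it in self.items:
            if not isinstance(it.weight, (int, np.integer)) or it.weight < 1:
                raise SchemaError(f"item {it.id!r}: weight must be a positive integer, got {it.weight!r}")
        if self.missing_policy not in MISSING_POLICIES:
            raise SchemaError(f"unknown missing_policy {self.missing_policy!r}")
        self._validate_bands()

    def _validate_bands(self) -> None:
        if not self.bands:
            raise SchemaError("definition has no bands")
        expected_lower = 0
        for i, b in enumerate(self.bands):
            last = i == len(self.bands) - 1
            if b.lower != expected_lower:
                raise SchemaError(
                    f"band {b.name!r}: lower bound {b.lower} leaves a gap/overlap (expected {expected_lower})"
                )
            if last:
                if b.upper is not None:
                    raise SchemaError(f"last band {b.name!r} must be unbounded above")
            else:
                if b.upper is None:
                    raise SchemaError(f"band {b.name!r}: only the last band may be unbounded")
                if b.upper < b.lower:
                    raise SchemaError(f"band {b.name!r}: upper {b.upper} < lower {b.lower}")
                expected_lower = b.upper + 1

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    @property
    def weights(self) -> dict[str, int]:
        return {it.id: it.weight for it in self.items}

    @property
    def max_score(self) -> int:
        """Maximum attainable score: the sum of the item weights."""
        return int(sum(it.weight for it in self.items))

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def with_weights(self, weights: Mapping[str, int]) -> "ChecklistDefinition":
        """Return a copy with the given item weights replaced."""
        unknown = set(weights) - set(self.item_ids)
        if unknown:
            raise SchemaError(f"unknown item ids in weight update: {sorted(unknown)}")
        items = tuple(
            ChecklistItem(it.id, it.label, int(weights.get(it.id, it.weight))) for it in self.items
        )
        return ChecklistDefinition(self.name, self.version, items, self.bands, self.missing_policy)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "missing_policy": self.missing_policy,
            "items": [{"id": i.id, "label": i.label, "weight": i.weight} for i in self.items],
            "bands": [{"name": b.name, "lower": b.lower, "upper": b.upper} for b in self.bands],
        }


def _definition_from_dict(doc: Mapping) -> ChecklistDefinition:
    try:
        items = tuple(
            ChecklistItem(str(d["id"]), str(d.get("label", d["id"])), d["weight"]) for d in doc["items"]
        )
        bands = tuple(Band(str(d["name"]), int(d["lower"]), None if d["upper"] is None else int(d["upper"])) for d in doc["bands"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed definition document: {exc}") from exc
    return ChecklistDefinition(
        name=str(doc.get("name", "")),
        version=str(doc.get("version", "")),
        items=items,
        bands=bands,
        missing_policy=str(doc.get("missing_policy", "absent_as_zero")),
    )


def load_definition(source: str | Path | Mapping) -> ChecklistDefinition:
    """Load a checklist definition from a JSON/YAML file path or a mapping.

    JSON is canonical; YAML is accepted (by extension ``.yaml``/``.yml``).
    """
    if isinstance(source, Mapping):
        return _definition_from_dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: definition document must be a mapping")
    return _definition_from_dict(doc)


def _load_packaged(name: str) -> ChecklistDefinition:
    doc = json.loads(resources.files("checkrisk.data").joinpath(name).read_text())
    return _definition_from_dict(doc)


def load_default_definition() -> ChecklistDefinition:
    """The packaged default 23-item checklist (max score 27)."""
    return _load_packaged("drs_checklist.json")


def load_sad_persons_definition() -> ChecklistDefinition:
    """The packaged 10-item SAD PERSONS scale (max score 10)."""
    return _load_packaged("sad_persons.json")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

_STATE_VALUES = {"present": 1, "absent": 0, "missing": 0, 1: 1, 0: 0, "1": 1, "0": 0}


def score_participant(
    responses: Mapping[str, object], definition: ChecklistDefinition
) -> int:
    """Score one participant.

    ``responses`` maps item_id to ``"present"``/``"absent"``/``"missing"`` (or
    1/0/``None``/NaN).  Missing responses contribute zero points.  A response
    for an item the definition does not contain is an error.
    """
    unknown = set(responses) - set(definition.item_ids)
    if unknown:
        raise ValueError(f"responses for unknown item ids: {sorted(unknown)}")
    total = 0
    weights = definition.weights
    for item_id, state in responses.items():
        if state is None or (isinstance(state, float) and np.isnan(state)):
            continue
        if state == MISSING_TOKEN:
            continue
        try:
            value = _STATE_VALUES[state]
        except (KeyError, TypeError):
            raise ValueError(f"item {item_id!r}: unrecognized response state {state!r}") from None
        total += weights[item_id] * value
    return total


def assign_band(score: int, definition: ChecklistDefinition) -> str:
    """Return the name of the unique band containing ``score``."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    for band in definition.bands:
        if band.contains(int(score)):
            return band.name
    raise AssertionError("bands are exhaustive by invariant")  # pragma: no cover


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

ITEM_PREFIX = "item_"
OUTCOME_COLUMN = "outcome"
ID_COLUMN = "participant_id"


def read_cohort(path: str | Path, definition: ChecklistDefinition | None = None) -> pd.DataFrame:
    """Read a cohort CSV/TSV.

    Expected columns: ``participant_id``, one ``item_<id>`` column per checklist
    item with values 0/1/NA (NA = missing response), ``outcome`` in {0,1}, and
    optional subgroup label columns.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN], keep_default_na=True)
    _validate_cohort(df, definition)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)


def _validate_cohort(df: pd.DataFrame, definition: ChecklistDefinition | None) -> None:
    if ID_COLUMN in df.columns and df[ID_COLUMN].duplicated().any():
        dup = df.loc[df[ID_COLUMN].duplicated(), ID_COLUMN].iloc[0]
        raise ValueError(f"duplicate participant_id {dup!r}")
    if OUTCOME_COLUMN not in df.columns:
        raise ValueError(f"cohort lacks required column {OUTCOME_COLUMN!r}")
    if df[OUTCOME_COLUMN].isna().any():
        raise ValueError("outcome must never be missing")
    if not df[OUTCOME_COLUMN].isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    if definition is not None:
        missing_cols = [f"{ITEM_PREFIX}{i}" for i in definition.item_ids if f"{ITEM_PREFIX}{i}" not in df.columns]
        if missing_cols:
            raise ValueError(f"cohort lacks item columns: {missing_cols}")


def item_columns(df: pd.DataFrame, definition: ChecklistDefinition) -> list[str]:
    return [f"{ITEM_PREFIX}{i}" for i in definition.item_ids]


@dataclass
class ScoredCohort:
    """Per-participant integer scores, band assignments, and summary moments.

    ``summary`` uses the sample standard deviation and the standard
    moment-based skewness and *excess* kurtosis.  ``n_missing`` counts missing
    item responses per participant; ``max_missing_fraction`` optionally drops
    participants whose missingness exceeds the threshold before scoring
    (a completeness rule some study protocols apply; off by default).
    """

    scores: np.ndarray
    bands: np.ndarray
    outcomes: np.ndarray
    n_missing: np.ndarray
    definition: ChecklistDefinition
    summary: dict = field(default_factory=dict)
    frame: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.scores)

    def band_counts(self) -> pd.Series:
        names = list(self.definition.band_names)
        counts = pd.Series(self.bands).value_counts()
        return counts.reindex(names, fill_value=0)


def _summary(scores: np.ndarray) -> dict:
    s = np.asarray(scores, dtype=float)
    mode = float(stats.mode(s, keepdims=False).mode) if len(s) else float("nan")
    return {
        "n": int(len(s)),
        "mean": float(np.mean(s)),
        "sd": float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
        "median": float(np.median(s)),
        "mode": mode,
        "skewness": float(stats.skew(s)) if len(s) > 2 else float("nan"),
        "kurtosis": float(stats.kurtosis(s)) if len(s) > 3 else float("nan"),
        "min": float(np.min(s)),
        "max": float(np.max(s)),
    }


def score_cohort(
    cohort: pd.DataFrame,
    definition: ChecklistDefinition,
    item_mask: Iterable[str] | None = None,
    max_missing_fraction: float | None = None,
) -> ScoredCohort:
    """Score every participant of a cohort over the (optionally masked) item set.

    ``item_mask``, when given, restricts scoring to that subset of item ids --
    the mechanism behind sensitivity analyses that exclude items assessed at a
    later study wave.  ``max_missing_fraction`` drops participants with more
    than that fraction of item responses missing (default: keep everyone).
    """
    _validate_cohort(cohort, definition)
    if item_mask is not None:
        mask = list(dict.fromkeys(item_mask))
        if not mask:
            raise ValueError("item_mask must not be empty")
        unknown = set(mask) - set(definition.item_ids)
        if unknown:
            raise ValueError(f"item_mask contains unknown item ids: {sorted(unknown)}")
    else:
        mask = list(definition.item_ids)

    cols = [f"{ITEM_PREFIX}{i}" for i in definition.item_ids]
    values = cohort[cols].to_numpy(dtype=float)
    n_missing = np.isnan(values).sum(axis=1).astype(int)

    if max_missing_fraction is not None:
        keep = n_missing <= max_missing_fraction * len(definition.item_ids)
        cohort = cohort.loc[keep].reset_index(drop=True)
        values = values[keep]
        n_missing = n_missing[keep]

    weights = definition.weights
    w = np.array([weights[i] if i in mask else 0 for i in definition.item_ids], dtype=float)
    present = np.nan_to_num(values, nan=0.0)  # missing responses score zero
    if not np.isin(present, (0.0, 1.0)).all():
        raise ValueError("item responses must be 0, 1, or NA")
    scores = (present @ w).astype(int)
    bands = np.array([assign_band(s, definition) for s in scores])
    outcomes = cohort[OUTCOME_COLUMN].to_numpy(dtype=int)
    return ScoredCohort(
        scores=scores,
        bands=bands,
        outcomes=outcomes,
        n_missing=n_missing,
        definition=definition,
        summary=_summary(scores),
        frame=cohort,
    )
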