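"""Synthetic cohorts with the structure the checklist analyses assume.

Real development/validation cohorts for this kind of instrument are large
epidemiological samples with (i) correlated binary risk factors, (ii) a
right-skewed integer risk score, and (iii) a rare prospective outcome whose
log-odds rise linearly with the score.  The generator reproduces exactly that
structure with a single-factor Gaussian copula: a standard-normal latent trait
L per participant, item j present iff

    lambda * L + sqrt(1 - lambda^2) * e_j  >  Phi^{-1}(1 - p_j),

so the marginal prevalence of item j is exactly ``p_j`` while the shared
loading ``lambda`` induces positive inter-item correlation (and hence the
over-dispersed, right-skewed score).  The outcome is Bernoulli with
``logit P = alpha + beta * score``.  Defaults target the published cohort
descriptors: score mean ~3.3, SD ~2.5 (loading calibrated by bisection),
positive skew, and a ~0.7-0.9% outcome prevalence under intercept -7.15 and
slope 0.41 at n = 18,024.

The module also packages the study's printed risk-group count tables as a
``FixtureSet`` so that every number derivable from the printed counts can be
recomputed without the (unavailable) raw cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .checklist import (
    ITEM_PREFIX,
    OUTCOME_COLUMN,
    ChecklistDefinition,
    load_default_definition,
)

__all__ = [
    "CohortSpec",
    "FixtureSet",
    "DEFAULT_PREVALENCES",
    "DEFAULT_LOADING",
    "default_spec",
    "simulate_cohort",
    "simulate_item_effect_cohort",
    "calibrate_loading",
    "independent_score_sd",
    "load_fixtures",
]

#: Default marginal prevalences for the 23 items, chosen to be typical
#: general-population values for each construct; the implied weighted-score
#: mean is ~3.3.  The published cohort descriptors are matched jointly with
#: the latent loading below.
DEFAULT_PREVALENCES: dict[str, float] = {
    "attempt_lifetime": 0.026,
    "hosp_past_year": 0.010,
    "hosp_lifetime": 0.060,
    "nssi_lifetime": 0.030,
    "ideation_past_year": 0.030,
    "ideation_lifetime": 0.140,
    "bpd_lifetime": 0.060,
    "unemployed": 0.050,
    "poor_health": 0.150,
    "lower_income": 0.500,
    "child_physical_abuse": 0.080,
    "sexual_abuse": 0.100,
    "sleep_problems": 0.100,
    "ptsd_past_year": 0.040,
    "mood_disorder": 0.200,
    "violence_incarceration": 0.120,
    "weekly_binges": 0.080,
    "current_smoker": 0.250,
    "sud_past_year": 0.100,
    "under_35": 0.300,
    "less_than_hs": 0.150,
    "sexual_minority": 0.020,
    "female_sex": 0.580,
}

#: Single-factor loading calibrated (via ``calibrate_loading``, target SD 2.5)
#: for the default prevalences and item weights.
DEFAULT_LOADING: float = 0.416

#: Outcome model defaults: the published combined-validation logistic fit.
DEFAULT_INTERCEPT: float = -7.15
DEFAULT_SLOPE: float = 0.41
DEFAULT_N: int = 18024


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n: int
    item_prevalences: dict[str, float]
    latent_loading: float
    outcome_intercept: float
    outcome_slope: float
    seed: int
    definition: ChecklistDefinition = field(default_factory=load_default_definition)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0 <= self.latent_loading < 1:
            raise ValueError("latent loading must be in [0, 1)")
        ids = set(self.definition.item_ids)
        if set(self.item_prevalences) != ids:
            raise ValueError("need exactly one prevalence per definition item")
        for item_id, p in self.item_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {item_id!r} must be in (0, 1), got {p}")


def default_spec(seed: int = 0, n: int = DEFAULT_N, **overrides) -> CohortSpec:
    """The packaged default spec: 23 items, calibrated loading, published
    outcome intercept/slope, n = 18,024."""
    kwargs = dict(
        n=n,
        item_prevalences=dict(DEFAULT_PREVALENCES),
        latent_loading=DEFAULT_LOADING,
        outcome_intercept=DEFAULT_INTERCEPT,
        outcome_slope=DEFAULT_SLOPE,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _draw_items(rng: np.random.Generator, n: int, prevalences: np.ndarray, loading: float) -> np.ndarray:
    thresholds = ndtri(1.0 - prevalences)  # P(latent > thr) = p
    latent = rng.standard_normal(n)
    noise = rng.standard_normal((n, len(prevalences)))
    underlying = loading * latent[:, None] + np.sqrt(1.0 - loading**2) * noise
    return (underlying > thresholds[None, :]).astype(np.int8)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table: item indicators plus a score-driven rare outcome.

    All randomness flows from ``spec.seed`` through two spawned child streams
    (items, outcome), so the draws are independently reproducible.
    """
    children = np.random.SeedSequence(spec.seed).spawn(2)
    rng_items = np.random.default_rng(children[0])
    rng_outcome = np.random.default_rng(children[1])

    item_ids = spec.definition.item_ids
    prev = np.array([spec.item_prevalences[i] for i in item_ids])
    items = _draw_items(rng_items, spec.n, prev, spec.latent_loading)

    weights = np.array([spec.definition.weights[i] for i in item_ids], dtype=float)
    scores = items @ weights
    p_outcome = expit(spec.outcome_intercept + spec.outcome_slope * scores)
    outcome = (rng_outcome.random(spec.n) < p_outcome).astype(int)

    df = pd.DataFrame(items, columns=[f"{ITEM_PREFIX}{i}" for i in item_ids])
    df.insert(0, "participant_id", [f"P{k:06d}" for k in range(spec.n)])
    df[OUTCOME_COLUMN] = outcome
    return df


def simulate_item_effect_cohort(
    n: int,
    prevalences: np.ndarray,
    loading: float,
    coefs: np.ndarray,
    intercept: float,
    seed: int,
    item_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort whose outcome depends on the items directly (one log-odds
    coefficient per item) rather than through a predefined score.

    Used for methodological experiments -- e.g. testing whether forward
    selection recovers truly informative items among null ones.
    """
    prevalences = np.asarray(prevalences, dtype=float)
    coefs = np.asarray(coefs, dtype=float)
    if prevalences.shape != coefs.shape:
        raise ValueError("one coefficient per item required")
    children = np.random.SeedSequence(seed).spawn(2)
    items = _draw_items(np.random.default_rng(children[0]), n, prevalences, loading)
    p = expit(intercept + items @ coefs)
    outcome = (np.random.default_rng(children[1]).random(n) < p).astype(int)
    if item_ids is None:
        item_ids = [f"v{j:02d}" for j in range(len(prevalences))]
    df = pd.DataFrame(items, columns=[f"{ITEM_PREFIX}{i}" for i in item_ids])
    df.insert(0, "participant_id", [f"P{k:06d}" for k in range(n)])
    df[OUTCOME_COLUMN] = outcome
    return df


def independent_score_sd(spec: CohortSpec) -> float:
    """Closed-form score SD when the loading is zero (independent items):
    sqrt(sum w_j^2 p_j (1 - p_j))."""
    w = np.array([spec.definition.weights[i] for i in spec.definition.item_ids], dtype=float)
    p = np.array([spec.item_prevalences[i] for i in spec.definition.item_ids])
    return float(np.sqrt(np.sum(w**2 * p * (1 - p))))


def _simulated_sd(spec: CohortSpec, loading: float, n: int, seed: int) -> float:
    probe = replace(spec, n=n, latent_loading=loading, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    item_ids = probe.definition.item_ids
    prev = np.array([probe.item_prevalences[i] for i in item_ids])
    items = _draw_items(rng, n, prev, loading)
    w = np.array([probe.definition.weights[i] for i in item_ids], dtype=float)
    return float(np.std(items @ w, ddof=1))


def calibrate_loading(
    spec: CohortSpec,
    target_sd: float,
    tol: float = 0.05,
    n: int = 50_000,
    inner_seed: int = 1_234_567,
    max_iter: int = 40,
) -> float:
    """Bisection on the latent loading until the simulated score SD matches
    ``target_sd`` within ``tol``.

    The score SD is non-decreasing in the loading (more shared variance means
    more positive inter-item correlation), which the bisection exploits.  The
    probe simulations use a fixed internal seed so the calibration is
    deterministic.  Raises if the target lies outside the achievable range
    [SD(loading=0), SD(loading=0.95)].
    """
    lo, hi = 0.0, 0.95
    sd_lo = _simulated_sd(spec, lo, n, inner_seed)
    sd_hi = _simulated_sd(spec, hi, n, inner_seed)
    if not sd_lo - tol <= target_sd <= sd_hi + tol:
        raise ValueError(
            f"target SD {target_sd} unreachable; achievable range is "
            f"[{sd_lo:.3f}, {sd_hi:.3f}] for these prevalences"
        )
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        sd_mid = _simulated_sd(spec, mid, n, inner_seed)
        if abs(sd_mid - target_sd) <= tol:
            return mid
        if sd_mid < target_sd:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# Printed-count fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSet:
    """The published risk-group count tables and derived confusion matrices.

    ``band_lowers`` are the band lower bounds (0, 3, 6, 9, 12, 15); using them
    as representative scores reproduces any statistic that depends on scores
    only through the band partition (cuts 6 and 9 fall on band boundaries).
    """

    bands: tuple[str, ...]
    band_lowers: tuple[int, ...]
    development: pd.DataFrame
    validation: pd.DataFrame

    def counts(self, cohort: str) -> pd.DataFrame:
        if cohort == "pooled":
            dev, val = self.development, self.validation
            return pd.DataFrame(
                {
                    "controls": dev["controls"] + val["controls"],
                    "attempters": dev["attempters"] + val["attempters"],
                },
                index=dev.index,
            )
        return getattr(self, cohort)

    def confusion(self, cutoff: int, cohort: str = "pooled") -> tuple[int, int, int, int]:
        """(tp, fp, fn, tn) at a cutoff that coincides with a band boundary."""
        if cutoff not in self.band_lowers:
            raise ValueError(f"cutoff {cutoff} is not a band boundary {self.band_lowers}")
        counts = self.counts(cohort)
        above = np.array(self.band_lowers) >= cutoff
        tp = int(counts["attempters"][above].sum())
        fp = int(counts["controls"][above].sum())
        fn = int(counts["attempters"][~above].sum())
        tn = int(counts["controls"][~above].sum())
        return tp, fp, fn, tn

    def pseudo_scores(self, cohort: str = "pooled") -> tuple[np.ndarray, np.ndarray]:
        """Participant-level (scores, outcomes) expansion with each band
        represented by its lower bound."""
        counts = self.counts(cohort)
        scores, outcomes = [], []
        for lower, (_, row) in zip(self.band_lowers, counts.iterrows()):
            scores.extend([lower] * (int(row["controls"]) + int(row["attempters"])))
            outcomes.extend([0] * int(row["controls"]) + [1] * int(row["attempters"]))
        return np.array(scores), np.array(outcomes)


def load_fixtures() -> FixtureSet:
    """Load the packaged printed count tables, verifying totals on load."""
    doc = json.loads(resources.files("checkrisk.data").joinpath("printed_counts.json").read_text())
    bands = tuple(doc["bands"])
    lowers = tuple(int(r.split("-")[0].rstrip("+")) for r in doc["band_ranges"])
    frames = {}
    for cohort in ("development", "validation"):
        block = doc[cohort]
        df = pd.DataFrame(
            {"controls": block["controls"], "attempters": block["attempters"]},
            index=list(bands),
        )
        total = int(df.to_numpy().sum())
        if total != block["total"]:
            raise ValueError(
                f"packaging error: {cohort} counts sum to {total}, expected {block['total']}"
            )
        frames[cohort] = df
    fixtures = FixtureSet(bands, lowers, frames["development"], frames["validation"])
    # cross-check the printed cut-6 panel against the band aggregation
    for cohort in ("development", "validation"):
        panel = doc["cut6"][cohort]
        tp, fp, fn, tn = fixtures.confusion(6, cohort)
        if (tp, fp, fn, tn) != (
            panel["above_attempts"], panel["above_controls"],
            panel["below_attempts"], panel["below_controls"],
        ):
            raise ValueError(f"packaging error: cut-6 panel inconsistent for {cohort}")
    return fixtures
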