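# Methods

## Scoring model

A checklist definition is a set of dichotomous items with positive integer
weights and a partition of the non-negative integers into named risk bands.
The participant score is the weighted count of present items. Missing
responses contribute zero points: this mirrors how such instruments are
scored in routine practice, where an unassessed risk factor cannot add to the
score, and it keeps the score computable for any response pattern. The number
of missing items is reported per participant, and an optional completeness
filter (`max_missing_fraction`) can drop participants with excessive
missingness before analysis; it is off by default.

The packaged default definition has 23 items, four of them double-weighted
(lifetime suicide attempt, lifetime psychiatric hospitalization, lifetime
nonsuicidal self-injury, lifetime borderline personality disorder), so the
maximum attainable score is 27. The published top band is labelled "15–30";
since the sum of the shipped weights is 27, the top band is implemented as
unbounded above (≥15), which honours the printed band edges for every
attainable score and stays correct if a definition file overrides weights
upward. Distribution summaries use the sample SD and moment-based skewness
and *excess* kurtosis, the conventions under which the published cohort
descriptors (kurtosis near zero in one veteran cohort) are coherent.

## ROC and DeLong inference

The AUC is the tie-corrected Mann–Whitney probability, computed via midranks,
with ties counting ½ — mandatory for integer scores, where ties are massive.
Variance estimation uses DeLong's structural components: the placement values
`v10_i` (fraction of controls below case i) and `v01_j`, with
`var(AUC) = var(v10)/m + var(v01)/n`. Confidence intervals are Wald on the
AUC scale, truncated to [0, 1]; the published AUC intervals are symmetric,
which is consistent with this (untransformed) choice, and a logit-scale
interval was deliberately not made the default. The paired test uses the
DeLong covariance of the two placement vectors; a zero variance of the
difference (identical scores, or any strictly monotone transform) is an
exact tie, returned as z = 0, p = 1 rather than 0/0.

## Cut-point analysis and quality indices

A positive test is score ≥ k. The quality indices are chance-corrected
predictive values:

    k(1)   = (NPV − (1 − P)) / P
    k(0)   = (PPV − P) / (1 − P)
    k(0.5) = 2·k(1)·k(0) / (k(1) + k(0)),  0 when k(1) + k(0) = 0

where P is prevalence. These equal 1 for a perfect test and 0 for a test
independent of the outcome, and they reproduce every checkable printed value
at cuts 6 and 9 to 2 dp; the source literature for the k(r) family does not
print the formulas, so this reverse-engineered identification is documented
rather than cited. "Efficiency" is raw accuracy (tp+tn)/N. The optimal cut
maximizes Youden's J with ties resolved toward the lower cutoff (higher
sensitivity), the clinically conservative direction for a screen.

Concentration of risk flags whole score levels, never splitting a tied score
value: for a requested top fraction q the threshold is the smallest score
whose upper tail does not exceed q (or the smallest attainable tail above q
when the top level alone is larger), and the realized flagged fraction is
reported alongside the nominal q.

## Contingency analysis and logistic calibration

2×2 tables report RR and OR with Wald intervals on the log scale (z = 1.96)
and an uncorrected Pearson chi-squared test. The Wald convention was fixed by
checking it against the printed interval for the most extreme published table
(OR 1,845.6, CI 433.6–7,855.3, reproduced within 1% relative error); exact
or profile intervals do not reproduce those ends. A Haldane–Anscombe +0.5
option exists for zero cells but is off by default. The logistic fit is the
standard Newton/IRLS MLE (via statsmodels) with Nagelkerke's rescaling of the
Cox–Snell R²; the per-point OR is exp(slope) with a Wald interval. Complete
separation is flagged (`converged=False`) instead of raising, because the
diagnostic context usually wants to see the fit attempt.

Reported tables can be rounded under a "paper" profile (rates to 0.1%,
OR/RR to 1 dp, AUC and kappa-type indices to 2 dp); full precision is always
retained internally.

## Forward selection and weight doubling

Candidates enter strictly in descending literature-evidence order (totals
0–40 from two 0–10 category components and two {0, 6–10} top-predictor
components per outcome type), ties broken by the attempt-category component
and then lexicographically — deterministic by construction. A candidate is
retained iff (a) its bivariate AUC exceeds 0.5 in ≥1 development cohort,
(b) the cumulative AUC gains ≥ `min_gain` in ≥1 cohort, and (c) no cohort
loses more than `max_loss`. The published procedure states these criteria
qualitatively but not numerically; the defaults are declared here as
`min_gain = 0.001` (below the 0.01 resolution of a 2-dp AUC table, to avoid
rounding artifacts) and `max_loss = 0.01` (the size of the dips visible in
the published selection trajectory, e.g. 0.92→0.91). The original selection
also involved human-in-the-loop re-orderings of item variants; that is not
algorithmically reproducible and is approximated by this deterministic pass.
The doubling pass revisits designated top predictors in evidence order and
doubles a weight only when the same gain/loss bar is cleared; doubling the
sole retained item is a monotone transform and correctly never fires.

### Recovery experiment

The selection machinery is exercised on synthetic cohorts in which ground
truth is known: 3 cohorts of n = 12,000, 23 items from the copula generator
(loading 0.3, prevalences 0.05–0.35), 10 items raising the outcome log-odds
by 0.5 each (intercept −3.5, outcome prevalence ≈ 10%), 13 pure-noise items.
Evidence totals are assigned higher for the informative items (26–30 and
16–20) than the null items (1–13), mirroring the real setting, where
literature-evidence totals correlate positively with observed bivariate AUC.
The acceptance bar — ≥8/10 informative retained, ≤3/13 null retained — is the
package's definition of adequate recovery at these effect sizes. All sizes
were chosen once as realistic for this design; the experiment runs in a few
seconds per seed.

## Synthetic cohort generator

Per participant, a standard-normal latent trait L is drawn; item j is present
iff `λ·L + √(1−λ²)·e_j > Φ⁻¹(1−p_j)` with independent standard-normal noise
e_j, giving exact marginal prevalence p_j and a single-factor positive
inter-item correlation controlled by λ. The outcome is Bernoulli with
`logit P = α + β·score`. All randomness flows from one seed through spawned
child streams (items, outcome), so each component is independently
reproducible.

Defaults: the 23 default prevalences are typical general-population values
for each construct (e.g. lifetime suicide attempt 2.6%, lifetime mood
disorder 20%, female 58%, lower income 50%), chosen so the weighted-score
mean is ≈3.3; the loading λ = 0.416 was fixed by the module's own bisection
calibration (`calibrate_loading`, 50,000-draw probes, fixed internal seed)
to hit score SD 2.5; α = −7.15 and β = 0.41 are the published
combined-validation logistic coefficients, and n = 18,024 the validation
size. Under these defaults the simulated score has mean ≈ 3.35, SD ≈ 2.52,
skewness ≈ 1.1, observed maximum ≈ 20, and outcome prevalence ≈ 0.7% — all
inside the published descriptor ranges, though the skewness is somewhat below
the printed 1.8: a single common factor cannot fully reproduce the heavier
upper tail of the real data (a mixture/zero-inflated structure could, but is
out of scope). Consequently, passing tests demonstrate correct *machinery*
(parameter recovery, calibration closure, invariants) rather than
reproduction of full-data discrimination: the synthetic AUC (≈0.83) is below
the published 0.91/0.92, as expected when the outcome depends on the items
only through the score and dependence is single-factor.

The printed risk-group count tables are packaged verbatim and validated on
load (totals 17,630 / 18,024; cut-6 panel cross-checked against band sums).
Expanding each band to its lower-bound score reproduces exactly every
statistic that depends on scores only through the band partition — the
band-boundary cuts 6, 9, 12, 15 and the concentration-of-risk point at the
top ~15% — which is how the acceptance checks recompute the published
values without raw data.

## Numerical choices and limitations

- AUC tie handling is exact (midranks); no smoothing or binormal fitting.
- Logistic convergence: Newton, log-likelihood tolerance 1e−8, 100
  iterations, BFGS fallback.
- Calibration bisection: λ ∈ [0, 0.95], SD tolerance 0.05, monotonicity of
  SD in λ assumed (and tested).
- Degenerate inputs: single-class outcomes, empty margins, zero-event
  cohorts, and empty reference bands raise typed errors naming the undefined
  statistic; degenerate AUCs warn and collapse the CI.
- Problem sizes in tests and acceptance runs (e.g. 1,000 null replicates at
  n = 200 for the paired-test calibration; 20 refit replicates at n = 18,024;
  50,000-draw calibration probes) were chosen to keep Monte-Carlo error well
  below the tolerances being checked while completing in seconds to minutes.
- Survey design/weights, attrition, per-item outcome effects, and subgroup-
  specific data-generating differences are not modelled.
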