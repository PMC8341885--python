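"""Logistic calibration, 2x2 contingency analysis, and risk-group tables."""

import numpy as np
import pytest
from scipy.special import expit

import checkrisk as ck
from conftest import make_cohort


class TestFitLogistic:
    def test_uninformative_predictor_r2_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        fit = ck.fit_logistic(x, y)
        assert fit.nagelkerke_r2 == pytest.approx(0.0, abs=0.01)
        assert abs(fit.slope) < 3 * fit.slope_se + 0.05

    def test_parameter_recovery_at_published_design(self):
        """Simulating with the published intercept/slope and refitting recovers
        the slope within 3 estimated SEs."""
        spec = ck.default_spec(seed=13)  # alpha=-7.15, beta=0.41, n=18,024
        cohort = ck.simulate_cohort(spec)
        scored = ck.score_cohort(cohort, spec.definition)
        fit = ck.fit_logistic(scored.scores, scored.outcomes)
        assert fit.converged
        assert abs(fit.slope - 0.41) < 3 * fit.slope_se
        assert fit.odds_ratio == pytest.approx(np.exp(fit.slope))

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=500)
        y = (rng.random(500) < expit(-1 + 0.8 * x)).astype(int)
        a = ck.fit_logistic(x, y)
        b = ck.fit_logistic(x, y)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            ck.fit_logistic([1.0, 2.0], [1, 1])

    def test_complete_separation_flagged(self):
        x = np.array([0, 1, 2, 3, 10, 11, 12, 13], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = ck.fit_logistic(x, y)
        assert not fit.converged

    def test_matches_two_by_two_or_for_binary_exposure(self):
        a, b, c, d = 18, 42, 7, 93
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        fit = ck.fit_logistic(x, y)
        table = ck.two_by_two(a, b, c, d)
        assert fit.odds_ratio == pytest.approx(table.odds_ratio, rel=1e-4)

    def test_informative_predictor_raises_r2(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=3000)
        y = (rng.random(3000) < expit(-2 + 1.2 * x)).astype(int)
        informative = ck.fit_logistic(x, y)
        shuffled = ck.fit_logistic(rng.permutation(x), y)
        assert 0 <= shuffled.nagelkerke_r2 < informative.nagelkerke_r2 <= 1


class TestTwoByTwo:
    def test_published_highest_vs_lowest_validation(self):
        res = ck.two_by_two(32, 68, 2, 7844)
        assert round(res.odds_ratio, 1) == 1845.6
        assert res.or_ci[0] == pytest.approx(433.6, rel=0.01)
        assert res.or_ci[1] == pytest.approx(7855.3, rel=0.01)

    def test_published_low_vs_lowest_risk_ratio(self):
        res = ck.two_by_two(24, 7095, 2, 8055)
        assert round(res.risk_ratio, 1) == 13.6

    def test_published_cut6_validation_or(self):
        res = ck.two_by_two(133, 2689, 26, 15176)
        assert round(res.odds_ratio, 1) == 28.9

    def test_symmetric_table_is_null(self):
        res = ck.two_by_two(9, 9, 9, 9)
        assert res.odds_ratio == res.risk_ratio == 1.0
        assert res.chi_square == pytest.approx(0.0)

    def test_cis_contain_point_estimates(self):
        res = ck.two_by_two(30, 70, 10, 90)
        assert res.or_ci[0] < res.odds_ratio < res.or_ci[1]
        assert res.rr_ci[0] < res.risk_ratio < res.rr_ci[1]

    def test_chi_square_equals_brute_force(self):
        a, b, c, d = 12, 38, 25, 125
        res = ck.two_by_two(a, b, c, d)
        table = np.array([[a, b], [c, d]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        assert res.chi_square == pytest.approx(((table - expected) ** 2 / expected).sum())

    def test_zero_cell_infinite_or_haldane_option(self):
        res = ck.two_by_two(5, 0, 2, 98)
        assert np.isinf(res.odds_ratio)
        corrected = ck.two_by_two(5, 0, 2, 98, haldane=True)
        assert np.isfinite(corrected.odds_ratio)
        assert corrected.corrected


class TestRiskGroupTable:
    def _scored_from_fixture(self, fixtures, cohort):
        scores, outcomes = fixtures.pseudo_scores(cohort)
        definition = ck.load_default_definition()
        bands = np.array([ck.assign_band(s, definition) for s in scores])
        return ck.ScoredCohort(
            scores=scores, bands=bands, outcomes=outcomes,
            n_missing=np.zeros(len(scores), dtype=int),
            definition=definition,
        )

    def test_published_development_panel(self, fixtures):
        table = ck.risk_group_table(self._scored_from_fixture(fixtures, "development"))
        moderate = table[table["band"] == "Moderate risk"].iloc[0]
        assert round(moderate["odds_ratio"], 1) == 84.0
        assert round(moderate["risk_ratio"], 1) == 82.3
        total = table[table["band"] == "Total"].iloc[0]
        assert total["total"] == 17630

    def test_reference_band_is_unity(self, fixtures):
        table = ck.risk_group_table(self._scored_from_fixture(fixtures, "validation"))
        lowest = table.iloc[0]
        assert lowest["risk_ratio"] == 1.0 and lowest["odds_ratio"] == 1.0

    def test_band_totals_sum_to_cohort(self, fixtures):
        table = ck.risk_group_table(self._scored_from_fixture(fixtures, "pooled"))
        bands_only = table[table["band"] != "Total"]
        assert bands_only["total"].sum() == 35654
        assert bands_only["cumulative_pct"].iloc[-1] == pytest.approx(1.0)

    def test_single_band_cohort(self, fixtures):
        definition = ck.load_default_definition()
        scores = np.zeros(10, dtype=int)
        scored = ck.ScoredCohort(
            scores=scores,
            bands=np.array([ck.assign_band(s, definition) for s in scores]),
            outcomes=np.array([0] * 9 + [1]),
            n_missing=np.zeros(10, dtype=int),
            definition=definition,
        )
        table = ck.risk_group_table(scored)
        lowest = table.iloc[0]
        assert lowest["pct_of_sample"] == pytest.approx(1.0)


class TestSubgroupAuc:
    def test_identical_subgroups_identical_auc(self, definition):
        cohort = ck.simulate_cohort(ck.default_spec(seed=16, n=4000))
        doubled = cohort.copy()
        doubled["grp"] = "a"
        other = cohort.copy()
        other["grp"] = "b"
        other["participant_id"] = other["participant_id"] + "b"
        import pandas as pd

        both = pd.concat([doubled, other], ignore_index=True)
        res = ck.subgroup_auc(both, definition, "grp")
        assert res["a"].auc == pytest.approx(res["b"].auc)

    def test_pooled_equals_ungrouped(self, definition):
        cohort = ck.simulate_cohort(ck.default_spec(seed=17, n=6000))
        cohort["grp"] = "all"
        scored = ck.score_cohort(cohort, definition)
        pooled = ck.auc_delong(scored.scores, scored.outcomes)
        res = ck.subgroup_auc(cohort, definition, "grp")
        assert res["all"].auc == pytest.approx(pooled.auc)

    def test_group_without_both_classes_skipped(self, definition):
        cohort = ck.simulate_cohort(ck.default_spec(seed=18, n=3000))
        cohort["grp"] = np.where(cohort["outcome"] == 1, "events_only", "mixed")
        res = ck.subgroup_auc(cohort, definition, "grp")
        assert res["events_only"] is None

    def test_label_independent_of_data_matches_pooled(self, definition):
        cohort = ck.simulate_cohort(ck.default_spec(seed=19, n=12000))
        rng = np.random.default_rng(20)
        cohort["grp"] = rng.choice(["x", "y"], size=len(cohort))
        scored = ck.score_cohort(cohort, definition)
        pooled = ck.auc_delong(scored.scores, scored.outcomes)
        for res in ck.subgroup_auc(cohort, definition, "grp").values():
            assert res is not None
            assert res.auc == pytest.approx(pooled.auc, abs=3 * pooled.standard_error + 0.03)
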