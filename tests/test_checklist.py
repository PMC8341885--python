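"""Checklist definition loading, scoring, banding, and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

import checkrisk as ck
from checkrisk.checklist import SchemaError
from conftest import make_cohort


class TestDefinitions:
    def test_default_definition_shape(self, definition):
        assert len(definition.items) == 23
        assert definition.max_score == 27
        doubled = [i.id for i in definition.items if i.weight == 2]
        assert sorted(doubled) == [
            "attempt_lifetime", "bpd_lifetime", "hosp_lifetime", "nssi_lifetime",
        ]

    def test_sad_persons_definition(self):
        sps = ck.load_sad_persons_definition()
        assert len(sps.items) == 10
        assert all(i.weight == 1 for i in sps.items)
        assert sps.max_score == 10

    def test_duplicate_item_ids_rejected(self, definition):
        doc = definition.to_dict()
        doc["items"].append(dict(doc["items"][0]))
        with pytest.raises(SchemaError, match="duplicate"):
            ck.load_definition(doc)

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda d: d["items"][0].update(weight=0), "weight"),
            (lambda d: d["bands"][1].update(lower=4), "gap/overlap"),
            (lambda d: d["bands"][-1].update(upper=30), "unbounded"),
            (lambda d: d.update(missing_policy="impute"), "missing_policy"),
        ],
    )
    def test_schema_errors_name_offending_field(self, definition, mutate, match):
        doc = definition.to_dict()
        mutate(doc)
        with pytest.raises(SchemaError, match=match):
            ck.load_definition(doc)

    def test_yaml_round_trip(self, definition, tmp_path):
        import yaml

        path = tmp_path / "def.yaml"
        path.write_text(yaml.safe_dump(definition.to_dict()))
        loaded = ck.load_definition(path)
        assert loaded.max_score == definition.max_score
        assert loaded.item_ids == definition.item_ids


class TestScoring:
    def test_all_absent_scores_zero(self, definition):
        assert ck.score_participant({i: 0 for i in definition.item_ids}, definition) == 0

    def test_double_weighted_item_alone(self, definition):
        assert ck.score_participant({"attempt_lifetime": 1}, definition) == 2

    def test_all_present_hits_max(self, definition):
        responses = {i: 1 for i in definition.item_ids}
        assert ck.score_participant(responses, definition) == 27

    def test_missing_treated_as_absent(self, definition):
        with_missing = {"attempt_lifetime": 1, "mood_disorder": None, "under_35": "NA"}
        assert ck.score_participant(with_missing, definition) == 2

    def test_unknown_item_rejected(self, definition):
        with pytest.raises(ValueError, match="unknown item"):
            ck.score_participant({"not_an_item": 1}, definition)

    def test_adding_present_item_is_monotone(self, definition):
        base = {"mood_disorder": 1}
        s0 = ck.score_participant(base, definition)
        for item in definition.item_ids:
            if item in base:
                continue
            s1 = ck.score_participant({**base, item: 1}, definition)
            assert s1 >= s0


class TestBands:
    @pytest.mark.parametrize(
        "score, band",
        [(0, "Lowest risk"), (2, "Lowest risk"), (3, "Low risk"), (6, "Moderate risk"),
         (11, "High risk"), (14, "Very high risk"), (15, "Highest risk"), (22, "Highest risk")],
    )
    def test_band_assignment(self, definition, score, band):
        assert ck.assign_band(score, definition) == band

    def test_bands_partition_scores(self, definition):
        counts = {}
        for s in range(0, 28):
            counts[ck.assign_band(s, definition)] = counts.get(ck.assign_band(s, definition), 0) + 1
        assert sum(counts.values()) == 28


class TestScoreCohort:
    def test_single_all_absent(self, definition):
        cohort = make_cohort(definition, [{}], [0])
        scored = ck.score_cohort(cohort, definition)
        assert list(scored.scores) == [0]
        assert scored.summary["mean"] == 0.0

    def test_matches_participant_scoring(self, definition, tiny_cohort):
        scored = ck.score_cohort(tiny_cohort, definition)
        for idx, row in tiny_cohort.iterrows():
            responses = {
                i: row[f"item_{i}"] for i in definition.item_ids
            }
            assert scored.scores[idx] == ck.score_participant(responses, definition)

    def test_mask_of_universally_absent_item_changes_nothing(self, definition, tiny_cohort):
        tiny_cohort["item_sexual_minority"] = 0
        full = ck.score_cohort(tiny_cohort, definition)
        masked = ck.score_cohort(
            tiny_cohort, definition,
            item_mask=[i for i in definition.item_ids if i != "sexual_minority"],
        )
        assert (full.scores == masked.scores).all()

    def test_empty_mask_rejected(self, definition, tiny_cohort):
        with pytest.raises(ValueError, match="mask"):
            ck.score_cohort(tiny_cohort, definition, item_mask=[])

    def test_scoring_is_pure(self, definition, tiny_cohort):
        a = ck.score_cohort(tiny_cohort, definition)
        b = ck.score_cohort(tiny_cohort, definition)
        assert (a.scores == b.scores).all()
        assert (a.bands == b.bands).all()
        assert a.summary == b.summary

    def test_band_counts_sum_to_cohort_size(self, definition, tiny_cohort):
        scored = ck.score_cohort(tiny_cohort, definition)
        assert scored.band_counts().sum() == len(tiny_cohort)

    def test_missing_counted_and_scored_zero(self, definition):
        cohort = make_cohort(definition, [{"attempt_lifetime": 1}], [0])
        cohort.loc[0, "item_mood_disorder"] = np.nan
        scored = ck.score_cohort(cohort, definition)
        assert scored.scores[0] == 2
        assert scored.n_missing[0] == 1

    def test_completeness_filter_drops_sparse_rows(self, definition):
        cohort = make_cohort(definition, [{}, {}], [0, 1])
        item_cols = [c for c in cohort.columns if c.startswith("item_")]
        cohort.loc[0, item_cols[:10]] = np.nan  # 10/23 ~ 43% missing
        scored = ck.score_cohort(cohort, definition, max_missing_fraction=0.35)
        assert len(scored) == 1

    def test_default_synthetic_cohort_hits_published_moments(self, definition):
        cohort = ck.simulate_cohort(ck.default_spec(seed=11))
        scored = ck.score_cohort(cohort, definition)
        assert scored.summary["mean"] == pytest.approx(3.3, abs=0.3)
        assert scored.summary["sd"] == pytest.approx(2.5, abs=0.3)
        assert scored.summary["skewness"] > 0


class TestCohortIO:
    def test_round_trip_preserves_missing(self, definition, tmp_path):
        cohort = make_cohort(definition, [{"attempt_lifetime": 1}, {}], [1, 0])
        cohort.loc[1, "item_mood_disorder"] = np.nan
        path = tmp_path / "cohort.csv"
        ck.write_cohort(cohort, path)
        loaded = ck.read_cohort(path, definition)
        assert loaded["item_mood_disorder"].isna().tolist() == [False, True]

    def test_outcome_must_be_complete_binary(self, definition, tmp_path):
        cohort = make_cohort(definition, [{}], [0])
        cohort["outcome"] = [2]
        path = tmp_path / "bad.csv"
        cohort.to_csv(path, index=False)
        with pytest.raises(ValueError, match="binary"):
            ck.read_cohort(path, definition)

    def test_duplicate_participant_ids_rejected(self, definition, tmp_path):
        cohort = make_cohort(definition, [{}, {}], [0, 1])
        cohort["participant_id"] = ["P1", "P1"]
        path = tmp_path / "dup.csv"
        cohort.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate participant_id"):
            ck.read_cohort(path, definition)
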