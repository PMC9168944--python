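from __future__ import annotations

import numpy as np
import pytest

from rehabcompass import (
    DefinitionError,
    ResponseValidationError,
    ScoringError,
    load_instrument_catalog,
    normalize_score,
    score_domain,
    score_instrument,
    validate_responses,
)
from rehabcompass.instruments import default_instrument_paths

from conftest import best_answers, make_record, random_answers, worst_answers
from oracle import ref_domain_score


class TestCatalogLoading:
    def test_packaged_defaults(self, catalog):
        assert set(catalog) == {
            "sis3", "sis_plus", "hads", "fas", "smrsq", "eq5d3l", "eat10",
        }

    def test_empty_file_set_gives_empty_catalog(self):
        assert load_instrument_catalog([]) == {}

    def test_default_item_counts(self, catalog):
        assert len(catalog["sis3"].items) == 60  # 59 ordinal items + recovery
        assert len(catalog["hads"].items) == 14
        assert len(catalog["fas"].items) == 10
        assert len(catalog["eat10"].items) == 10
        assert len(catalog["smrsq"].items) == 5
        assert len(catalog["eq5d3l"].items) == 6

    def test_duplicate_instrument_id_rejected(self):
        path = default_instrument_paths()[0]
        with pytest.raises(DefinitionError, match="duplicate instrument id"):
            load_instrument_catalog([path, path])

    def test_item_in_two_domains_rejected(self):
        doc = {
            "instrument_id": "x",
            "scoring_rule": "mean-rescale",
            "higher_is_better": True,
            "domains": [
                {"domain_id": "a", "raw_min": 1, "raw_max": 5,
                 "items": [{"item_id": "i1", "levels": {"min": 1, "max": 5}}]},
                {"domain_id": "b", "raw_min": 1, "raw_max": 5,
                 "items": [{"item_id": "i1", "levels": {"min": 1, "max": 5}}]},
            ],
        }
        with pytest.raises(DefinitionError, match="more than one domain"):
            load_instrument_catalog([doc])

    @pytest.mark.parametrize("field,value,msg", [
        ("domains", [], "domain"),
        ("scoring_rule", "bogus-rule", "scoring_rule"),
    ])
    def test_schema_violations_are_descriptive(self, field, value, msg):
        doc = {
            "instrument_id": "x",
            "scoring_rule": "mean-rescale",
            "higher_is_better": True,
            "domains": [
                {"domain_id": "a", "raw_min": 1, "raw_max": 5,
                 "items": [{"item_id": "i1", "levels": {"min": 1, "max": 5}}]},
            ],
        }
        doc[field] = value
        with pytest.raises(DefinitionError, match=msg):
            load_instrument_catalog([doc])

    def test_bad_raw_bounds_rejected(self):
        doc = {
            "instrument_id": "x",
            "scoring_rule": "mean-rescale",
            "higher_is_better": True,
            "domains": [
                {"domain_id": "a", "raw_min": 5, "raw_max": 5,
                 "items": [{"item_id": "i1", "levels": {"min": 1, "max": 5}}]},
            ],
        }
        with pytest.raises(DefinitionError, match="raw_min"):
            load_instrument_catalog([doc])


class TestValidation:
    def test_hads_all_admissible(self, catalog):
        hads = catalog["hads"]
        rec = make_record(hads, {it.item_id: 2 for it in hads.items})
        assert validate_responses(rec, hads) is rec

    def test_fas_out_of_range_code(self, catalog):
        fas = catalog["fas"]
        answers = {it.item_id: 3 for it in fas.items}
        answers["fas1"] = 7
        rec = make_record(fas, answers)
        with pytest.raises(ResponseValidationError, match="fas1.*7"):
            validate_responses(rec, fas)

    def test_unknown_item_id(self, catalog):
        sis = catalog["sis3"]
        rec = make_record(sis, {"sis9z": 3})
        with pytest.raises(ResponseValidationError, match="sis9z"):
            validate_responses(rec, sis)

    def test_explicit_missing_is_preserved(self, catalog):
        hads = catalog["hads"]
        rec = make_record(hads, {"hads_a1": None, "hads_a2": 1})
        out = validate_responses(rec, hads)
        assert out.answers["hads_a1"] is None


class TestNormalizeScore:
    def test_anchors(self):
        assert normalize_score(5, (1, 5), True) == 100
        assert normalize_score(1, (1, 5), True) == 0
        assert normalize_score(50, (10, 50), False) == 0
        assert normalize_score(10, (10, 50), False) == 100

    def test_midpoint_linearity(self):
        assert normalize_score(3, (1, 5), True) == 50
        assert normalize_score(30, (10, 50), False) == 50

    def test_out_of_bounds_raises(self):
        with pytest.raises(ScoringError, match="outside bounds"):
            normalize_score(6, (1, 5), True)


class TestScoreDomain:
    def test_sis_strength_all_best_is_100(self, catalog):
        sis = catalog["sis3"]
        rec = make_record(sis, best_answers(sis))
        assert score_domain(rec, sis, "strength").normalized == 100

    def test_fas_all_worst_is_0(self, catalog):
        fas = catalog["fas"]
        rec = make_record(fas, {it.item_id: 5 for it in fas.items})
        out = score_domain(rec, fas, "fatigue")
        assert out.raw == 50
        assert out.normalized == 0

    def test_fas_raw_22_normalizes_to_70(self, catalog):
        # 100 * (50 - 22) / 40 = 70, frozen from direct evaluation of the
        # linear rescale
        fas = catalog["fas"]
        answers = {f"fas{i}": 2 for i in range(1, 9)}  # 8 x 2 = 16
        answers.update({"fas9": 3, "fas10": 3})  # + 6 -> 22
        rec = make_record(fas, answers)
        out = score_domain(rec, fas, "fatigue")
        assert out.raw == 22
        assert out.normalized == pytest.approx(70)

    def test_fas_rescale_monotone_over_coarse_grid(self, catalog):
        # exhaustive over all constant response vectors: raw 10..50 step 10
        fas = catalog["fas"]
        norms = []
        for level in (1, 2, 3, 4, 5):
            rec = make_record(fas, {it.item_id: level for it in fas.items})
            norms.append(score_domain(rec, fas, "fatigue").normalized)
        assert norms == sorted(norms, reverse=True)

    def test_unknown_domain_raises(self, catalog):
        sis = catalog["sis3"]
        rec = make_record(sis, best_answers(sis))
        with pytest.raises(ScoringError, match="nope"):
            score_domain(rec, sis, "nope")

    def test_proration_above_floor(self, catalog):
        # 5 of 9 emotion items answered (>= 50%): prorated mean over answered
        sis = catalog["sis3"]
        answers = {f"sis3_{i}": 3 for i in range(1, 6)}
        rec = make_record(sis, answers)
        out = score_domain(rec, sis, "emotion")
        assert not out.missing
        assert out.raw == pytest.approx(3.0)
        assert out.n_items_answered == 5 and out.n_items_total == 9

    def test_below_proration_floor_is_missing(self, catalog):
        sis = catalog["sis3"]
        rec = make_record(sis, {"sis3_1": 3})  # 1 of 9
        out = score_domain(rec, sis, "emotion")
        assert out.missing and out.normalized is None and not out.impaired

    def test_prorated_sum_rescale(self, catalog):
        # HADS anxiety, 4 of 7 answered at 1 -> prorated sum = 1 * 7 = 7
        hads = catalog["hads"]
        rec = make_record(hads, {f"hads_a{i}": 1 for i in range(1, 5)})
        out = score_domain(rec, hads, "anxiety")
        assert out.raw == pytest.approx(7.0)
        assert out.normalized == pytest.approx(100 * (21 - 7) / 21)

    def test_impaired_flag(self, catalog):
        hads = catalog["hads"]
        rec = make_record(hads, {it.item_id: 0 for it in hads.items})
        assert score_domain(rec, hads, "anxiety").impaired is False
        rec2 = make_record(hads, {**{it.item_id: 0 for it in hads.items},
                                  "hads_a1": 1})
        assert score_domain(rec2, hads, "anxiety").impaired is True


class TestSmrsqGrade:
    @pytest.mark.parametrize("grade", [0, 1, 2, 3, 4, 5])
    def test_grade_cascade(self, catalog, grade):
        smrsq = catalog["smrsq"]
        answers = {
            it.item_id: (1 if (it.grade or 0) == grade else 0)
            for it in smrsq.items
        }
        out = score_domain(make_record(smrsq, answers), smrsq, "disability")
        assert out.raw == grade
        assert out.normalized == pytest.approx(100 * (5 - grade) / 5)

    def test_first_yes_in_severity_order_wins(self, catalog):
        smrsq = catalog["smrsq"]
        answers = {it.item_id: 1 for it in smrsq.items}  # all yes
        out = score_domain(make_record(smrsq, answers), smrsq, "disability")
        assert out.raw == 5

    def test_missing_before_first_yes_resolves_to_missing(self, catalog):
        smrsq = catalog["smrsq"]
        answers = {it.item_id: 0 for it in smrsq.items}
        answers["smrsq5"] = None  # most severe question unanswered
        out = score_domain(make_record(smrsq, answers), smrsq, "disability")
        assert out.missing

    def test_missing_after_first_yes_is_resolved(self, catalog):
        smrsq = catalog["smrsq"]
        answers = {it.item_id: None for it in smrsq.items}
        answers["smrsq5"] = 1
        out = score_domain(make_record(smrsq, answers), smrsq, "disability")
        assert out.raw == 5


class TestEq5d:
    def test_dimension_rescale(self, catalog):
        eq = catalog["eq5d3l"]
        rec = make_record(eq, {"eq_mobility": 2})
        out = score_domain(rec, eq, "mobility")
        assert out.normalized == pytest.approx(50)

    def test_health_rating_passthrough(self, catalog):
        eq = catalog["eq5d3l"]
        rec = make_record(eq, {"eq_vas": 73})
        out = score_domain(rec, eq, "health_rating")
        assert out.raw == 73 and out.normalized == 73


class TestScoreInstrument:
    def test_all_best_sis_gives_nine_hundreds(self, catalog):
        sis = catalog["sis3"]
        rec = make_record(sis, best_answers(sis))
        scores = score_instrument(rec, sis)
        assert len(scores) == 9  # 8 ordinal domains + recovery rating
        assert all(s.normalized == 100 for s in scores)

    def test_empty_answers_all_missing(self, catalog):
        for definition in catalog.values():
            rec = make_record(definition, {})
            assert all(s.missing for s in score_instrument(rec, definition))

    def test_randomized_records_match_reference_scorer(self, catalog, rng):
        for _ in range(50):
            definition = catalog[
                sorted(catalog)[int(rng.integers(len(catalog)))]
            ]
            rec = make_record(
                definition, random_answers(definition, rng, missing_prob=0.15)
            )
            for s in score_instrument(rec, definition):
                raw, norm = ref_domain_score(
                    definition, s.domain_id, rec.answers
                )
                if s.missing:
                    assert raw is None
                else:
                    assert s.raw == raw
                    assert s.normalized == pytest.approx(norm, abs=1e-9)


class TestAnchoring:
    def test_all_best_yields_100_everywhere(self, catalog):
        for definition in catalog.values():
            rec = make_record(definition, best_answers(definition))
            for s in score_instrument(rec, definition):
                assert s.normalized == 100, (definition.instrument_id, s.domain_id)

    def test_all_worst_yields_0_everywhere(self, catalog):
        for definition in catalog.values():
            rec = make_record(definition, worst_answers(definition))
            for s in score_instrument(rec, definition):
                assert s.normalized == 0, (definition.instrument_id, s.domain_id)
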