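from __future__ import annotations

import numpy as np
import pytest

from rehabcompass import (
    CohortProfile,
    ResponseRecord,
    build_snapshots,
    default_catalog,
    generate_cohort,
    load_area_mapping,
    score_records,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def mapping(catalog):
    return load_area_mapping().validate_against_catalog(catalog)


def make_record(definition, answers, *, respondent="r01", timepoint="12-month",
                index=1):
    return ResponseRecord(
        respondent_id=respondent,
        timepoint=timepoint,
        timepoint_index=index,
        instrument_id=definition.instrument_id,
        answers=answers,
    )


def random_answers(definition, rng, missing_prob=0.0):
    """Uniform random admissible answers over every item of the instrument."""
    answers = {}
    for it in definition.items:
        if missing_prob and rng.random() < missing_prob:
            answers[it.item_id] = None
        else:
            answers[it.item_id] = int(rng.choice(it.codes))
    return answers


def best_answers(definition):
    return {it.item_id: definition.best_code_for(it) for it in definition.items}


def worst_answers(definition):
    return {it.item_id: definition.worst_code_for(it) for it in definition.items}


@pytest.fixture(scope="session")
def demo_profile():
    return CohortProfile(
        size=24,
        seed=11,
        mode="exact-count",
        prevalence={
            "fas:fatigue": 20 / 24,
            "sis_plus:sleep": 18 / 24,
            "hads:anxiety": 16 / 24,
            "sis3:strength": 17 / 24,
        },
    )


@pytest.fixture(scope="session")
def demo_snapshots(demo_profile, catalog, mapping):
    records = generate_cohort(demo_profile, catalog, mapping)
    rows = score_records(records, catalog)
    return build_snapshots(rows, mapping, timepoint="12-month")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
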