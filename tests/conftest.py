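"""Shared fixtures: one seeded design/survey reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from dcemcda import (
    PreferencePopulation,
    block_design,
    build_long_format,
    build_questionnaire,
    default_orphan_drug_schema,
    filter_survey,
    generate_defficient_design,
    simulate_responses,
)


@pytest.fixture(scope="session")
def schema():
    return default_orphan_drug_schema()


@pytest.fixture(scope="session")
def design30(schema):
    return generate_defficient_design(schema, n_sets=30, seed=7, n_restarts=2)


@pytest.fixture(scope="session")
def questionnaires(schema, design30):
    blocks = block_design(design30, n_blocks=3, seed=7)
    return [build_questionnaire(b, repeat_index=3, seed=i, block_id=i) for i, b in enumerate(blocks)]


@pytest.fixture(scope="session")
def survey84(schema, questionnaires):
    """Default 84-respondent simulated survey (15 careless by construction)."""
    return simulate_responses(questionnaires, PreferencePopulation(), 84, seed=11, schema=schema)


@pytest.fixture(scope="session")
def valid_survey(survey84):
    valid, _ = filter_survey(survey84)
    return valid


@pytest.fixture(scope="session")
def long_valid(valid_survey, schema):
    return build_long_format(valid_survey, schema)
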