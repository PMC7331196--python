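"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from stepredict.anthropometry import SubjectAnthropometry
from stepredict.preprocess import process_response
from stepredict.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def subject() -> SubjectAnthropometry:
    return SubjectAnthropometry(
        subject_id="S01",
        mass=75.0,
        height=1.80,
        com_height=0.99,
        foot_length=0.27,
        stance_width=0.25,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 40-trial cohort (default study conditions), processed."""
    config = GeneratorConfig(n_subjects=4, trials_per_subject=10, random_seed=1)
    responses, subjects = generate_cohort(config)
    by_id = {s.subject_id: s for s in subjects}
    processed = [process_response(r, by_id[r.subject_id]) for r in responses]
    return config, responses, subjects, processed


@pytest.fixture(scope="session")
def noiseless_cohort():
    """200 noiseless trials for label/event ground-truth checks."""
    config = GeneratorConfig(n_subjects=5, trials_per_subject=40, random_seed=3).noiseless()
    responses, subjects = generate_cohort(config)
    by_id = {s.subject_id: s for s in subjects}
    processed = [process_response(r, by_id[r.subject_id]) for r in responses]
    return config, responses, subjects, processed


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
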