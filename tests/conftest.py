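"""Shared fixtures: a small condition register with fitted rate models."""

import pytest

from saeratio.rate_models import fit_rate_model_pair
from saeratio.synthetic_data import (
    CohortConfig,
    ConditionProfile,
    SelectionModel,
    generate_cohort,
    generate_trial_suite,
)

COND = "copd"


@pytest.fixture(scope="session")
def register_config():
    return CohortConfig(
        n_persons=30_000,
        condition_profiles=(
            ConditionProfile(COND, 1.0, 69.1, 11.6, mm_mean_at_50=2.0),
        ),
        seed=123,
    )


@pytest.fixture(scope="session")
def register(register_config):
    """A 30k-person single-condition routine-care register."""
    return generate_cohort(register_config)


@pytest.fixture(scope="session")
def models_age_sex(register):
    return fit_rate_model_pair(register, COND, {"age"}, select_powers=False)


@pytest.fixture(scope="session")
def models_age_sex_mm(register):
    return fit_rate_model_pair(
        register, COND, {"age", "mm_count"}, select_powers=False
    )


@pytest.fixture(scope="session")
def trial_suite(register):
    """Eight null-selection trials of 400 participants (summaries + IPD)."""
    return generate_trial_suite(
        register, COND, SelectionModel(), n_trials=8, n_per_trial=400,
        followup_days=182.0, seed=99,
    )
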