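"""Shared fixtures: the bundled COVID-19 cohort tables and small synthetics."""

import pytest

from relw.data import (
    covid_ct_weight_bounds,
    covid_ct_weights,
    covid_symptom_counts,
    covid_symptom_weights,
)


@pytest.fixture(scope="session")
def symptom_counts():
    """15-variable symptom counting dataset (counts sum to 279, cohort 112)."""
    return covid_symptom_counts()


@pytest.fixture(scope="session")
def symptom_weights():
    """Published symptom weight table (sums to exactly 100.0%)."""
    return covid_symptom_weights()


@pytest.fixture(scope="session")
def ct_weights():
    """Published chest-CT weight table (19 findings, sums to 103.2%)."""
    return covid_ct_weights()


@pytest.fixture(scope="session")
def ct_bounds():
    """Chest-CT dataset in the min/max weight-bounds dialect."""
    return covid_ct_weight_bounds()
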