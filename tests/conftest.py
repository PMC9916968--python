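import pytest

from taavet.scoring import Rubric, default_rubric
from taavet.synthetic import (
    simulate_healthy_expression,
    simulate_tma_cohort,
    worked_example_annotations,
)


@pytest.fixture(scope="session")
def rubric() -> Rubric:
    return default_rubric()


@pytest.fixture(scope="session")
def worked_annotations():
    return worked_example_annotations()


@pytest.fixture(scope="session")
def healthy_profile_small():
    """A small healthy-tissue profile with known planted tiers (seed-fixed)."""
    return simulate_healthy_expression(n_low=8, n_medium=6, n_high=5, seed=11)


@pytest.fixture(scope="session")
def tma_cohort():
    """A 58-core TMA cohort with a planted hazard ratio of 3 (seed-fixed)."""
    return simulate_tma_cohort(seed=3, n_unassessable=5)
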