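import numpy as np
import pytest

from spinecea.params import (
    ClinicalParams,
    CostParams,
    LifeTable,
    TimingConvention,
    UtilitySet,
)


def flat_life_table(q: float) -> LifeTable:
    ages = np.arange(18, 101)
    return LifeTable(ages, np.full(ages.size, q))


@pytest.fixture(scope="session")
def zero_mortality() -> LifeTable:
    return flat_life_table(0.0)


@pytest.fixture(scope="session")
def default_life_table() -> LifeTable:
    return LifeTable.default()


@pytest.fixture
def base_clinical() -> ClinicalParams:
    return ClinicalParams()


@pytest.fixture
def base_utilities() -> UtilitySet:
    return UtilitySet()


@pytest.fixture
def base_costs() -> CostParams:
    return CostParams()


@pytest.fixture
def base_timing() -> TimingConvention:
    return TimingConvention()


def random_clinical(rng: np.random.Generator) -> ClinicalParams:
    """A random valid parameterisation for property tests."""
    return ClinicalParams(
        p_satisfactory_surgical=rng.uniform(0.3, 0.95),
        p_satisfactory_nonsurgical=rng.uniform(0.2, 0.9),
        p_satisfactory_after_revision=rng.uniform(0.3, 0.95),
        revision_rate_year1=rng.uniform(0.0, 0.25),
        revision_rate_subsequent=rng.uniform(0.0, 0.15),
        surgical_mortality=rng.uniform(0.0, 0.05),
        max_revisions=int(rng.integers(0, 4)),
    )


def random_utilities(rng: np.random.Generator) -> UtilitySet:
    lo, hi = sorted(rng.uniform(0.1, 1.0, size=2))
    return UtilitySet(satisfactory=hi, unsatisfactory=lo,
                      revision=rng.uniform(lo, hi))
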