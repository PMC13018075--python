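import numpy as np
import pytest

from pegsim import nominal_params
from pegsim.pk import individual_params
from pegsim.reference import load_growth_reference, load_igf1_reference


@pytest.fixture(scope="session")
def params():
    return nominal_params()


@pytest.fixture(scope="session")
def ind(params):
    """Typical individual at the reference weight (all etas zero)."""
    return individual_params(params.pk, params.pk.wt_ref)


@pytest.fixture(scope="session")
def igf1_ref():
    return load_igf1_reference()


@pytest.fixture(scope="session")
def growth_ref():
    return load_growth_reference()


@pytest.fixture(scope="session")
def ghd_cohort(params):
    from pegsim.cohort import generate_ghd_cohort

    return generate_ghd_cohort(n=292, seed=1, params=params)


@pytest.fixture(scope="session")
def banded_cohort():
    from pegsim.cohort import generate_banded_cohort

    return generate_banded_cohort(seed=1)
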