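import pytest

from vusquant import (
    fixture_table2a,
    fixture_vus_table5,
    fixture_vus_table6,
    load_default_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def table2a_cohort():
    return fixture_table2a(seed=17)


@pytest.fixture(scope="session")
def table5_cohort(catalog):
    return fixture_vus_table5(catalog)


@pytest.fixture(scope="session")
def table6_cohort(catalog):
    return fixture_vus_table6(catalog)
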