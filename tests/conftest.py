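import pytest

from lymphorad import (
    load_dose_table,
    load_err_parameters,
    make_background_table,
    make_cancer_rate_tables,
    make_toy_worked_example,
)


@pytest.fixture(scope="session")
def dose_table():
    return load_dose_table()


@pytest.fixture(scope="session")
def err_params():
    return load_err_parameters()


@pytest.fixture(scope="session")
def background():
    return make_background_table()


@pytest.fixture(scope="session")
def cancer_tables(background):
    return make_cancer_rate_tables(background=background)


@pytest.fixture()
def toy():
    return make_toy_worked_example()
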