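import pytest

from sdabkit.diversity import default_library_design
from sdabkit.scaffold import baseline_scaffold, humanized_scaffold
from sdabkit.simulate import generate_library, make_sanger_fixture


@pytest.fixture(scope="session")
def baseline():
    return baseline_scaffold()


@pytest.fixture(scope="session")
def humanized():
    return humanized_scaffold()


@pytest.fixture(scope="session")
def design():
    return default_library_design()


@pytest.fixture(scope="session")
def library_1k(design):
    return generate_library(design, 1000, seed=1)


@pytest.fixture(scope="session")
def library_10k(design):
    return generate_library(design, 10_000, seed=1)


@pytest.fixture(scope="session")
def sanger():
    """Packaged 315-clone QC fixture: (clones, truth table)."""
    return make_sanger_fixture()
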