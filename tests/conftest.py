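import pytest

from amplityper.catalog import define_types, designate_mains
from amplityper.synth import SimulationSpec, generate_dataset, paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture(scope="session")
def trnl(fixtures):
    return fixtures["trnL-trnF"]


@pytest.fixture(scope="session")
def rpl32(fixtures):
    return fixtures["rpl32-trnL"]


@pytest.fixture(scope="session")
def its(fixtures):
    return fixtures["ITS"]


def _catalog(fixture, marker, min_main_count=10):
    cat = define_types(fixture.condensed(), marker=marker, naming=fixture.naming)
    return designate_mains(cat, min_main_count=min_main_count)


@pytest.fixture(scope="session")
def trnl_catalog(trnl):
    return _catalog(trnl, "trnL-trnF")


@pytest.fixture(scope="session")
def rpl32_catalog(rpl32):
    return _catalog(rpl32, "rpl32-trnL")


@pytest.fixture(scope="session")
def its_catalog(its):
    return _catalog(its, "ITS")


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(SimulationSpec())
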