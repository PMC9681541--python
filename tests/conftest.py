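import pytest

from topoqspr import paper_data
from topoqspr.indices import INDEX_NAMES


@pytest.fixture(scope="session")
def ti_table():
    return paper_data.load_ti_table()[list(INDEX_NAMES)]


@pytest.fixture(scope="session")
def property_table():
    return paper_data.load_property_table()


@pytest.fixture(scope="session")
def worked_partitions():
    return paper_data.load_worked_partitions()


@pytest.fixture(scope="session")
def all_fits(ti_table, property_table):
    from topoqspr.qspr import fit_all

    return fit_all(ti_table, property_table, paper_data.MODELED_PROPERTIES)
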