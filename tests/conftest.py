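import pytest

from ocmrkit import fixtures as fx
from ocmrkit.ontology_model import TermId


@pytest.fixture(scope="session")
def toy_taxonomy():
    return fx.toy_taxonomy()


@pytest.fixture(scope="session")
def toy_lipid():
    return fx.toy_lipid()


@pytest.fixture(scope="session")
def toy_oae():
    return fx.toy_oae()


@pytest.fixture(scope="session")
def table1():
    return fx.table1_table()


@pytest.fixture(scope="session")
def table1_kg():
    return fx.table1_kg()


@pytest.fixture(scope="session")
def taxa():
    return {
        "eukaryota": TermId.parse("NCBITaxon:2759"),
        "bilateria": TermId.parse("NCBITaxon:33213"),
        "amniota": TermId.parse("NCBITaxon:32524"),
        "insecta": TermId.parse("NCBITaxon:50557"),
        "tiger": TermId.parse("NCBITaxon:9694"),
        "snake": TermId.parse("NCBITaxon:91950"),
        "silkworm": TermId.parse("NCBITaxon:7091"),
    }
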