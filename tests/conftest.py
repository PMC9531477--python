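import pytest

from selscan.io import load_fixture_table, load_fixture_tree
from selscan.simulate import make_or_reference_proteins, make_outgroup_gpcrs


@pytest.fixture(scope="session")
def table3():
    return load_fixture_table("table3")


@pytest.fixture(scope="session")
def table4():
    return load_fixture_table("table4")


@pytest.fixture()
def fixture_tree():
    return load_fixture_tree()


@pytest.fixture()
def heron_tree(fixture_tree):
    fixture_tree.set_foreground(["Nycticorax_nycticorax"])
    return fixture_tree


@pytest.fixture(scope="session")
def or_references():
    return make_or_reference_proteins(seed=7)


@pytest.fixture(scope="session")
def gpcr_outgroups():
    return make_outgroup_gpcrs(seed=8)
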