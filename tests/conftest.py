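import pytest

from invaphylo.occurrence_db import load_occurrence_database
from invaphylo.phylometrics import cophenetic_distances, read_newick
from invaphylo.synthetic_data import GeneratorConfig, make_fixture, simulate_database


def load_fixture(name, tmp_path):
    paths = make_fixture(name, tmp_path)
    db = load_occurrence_database(paths["occurrences"], paths["basins"])
    tree = read_newick(paths["tree"])
    return db, tree, paths


@pytest.fixture
def tiny(tmp_path):
    return load_fixture("tiny", tmp_path)


@pytest.fixture
def toy_country(tmp_path):
    return load_fixture("toy-country", tmp_path)


@pytest.fixture
def realm_scope_fixture(tmp_path):
    return load_fixture("realm-scope", tmp_path)


@pytest.fixture
def single_native_basin(tmp_path):
    return load_fixture("single-native-basin", tmp_path)


@pytest.fixture(scope="session")
def simulated():
    """One default-condition synthetic dataset shared across tests."""
    db, tree, truth = simulate_database(GeneratorConfig(seed=11))
    return db, tree, truth


@pytest.fixture(scope="session")
def tiny_tree():
    return read_newick("((A:1,B:1):1,C:2);", from_string=True)


@pytest.fixture(scope="session")
def tiny_D(tiny_tree):
    return cophenetic_distances(tiny_tree)
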