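import pytest

from scaffold_screen import datasets
from scaffold_screen.library_io import MoleculeRecord, ScaffoldQuery


@pytest.fixture(scope="session")
def docking_results():
    return datasets.load_docking_table()


@pytest.fixture(scope="session")
def docking_frame():
    return datasets.load_docking_frame()


@pytest.fixture(scope="session")
def descriptor_frame():
    return datasets.load_descriptor_frame()


@pytest.fixture(scope="session")
def thermo_records():
    return datasets.load_thermo_table()


@pytest.fixture(scope="session")
def hit_library():
    return datasets.load_hit_structures()


@pytest.fixture()
def scaffold_query():
    return ScaffoldQuery()


@pytest.fixture()
def record_factory():
    def make(smiles, id="X", name=None):
        return MoleculeRecord.from_smiles(smiles, id=id, name=name or id)
    return make
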