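import pytest
from rdkit import Chem

from stoned.fixtures import DRUGS, TOY


@pytest.fixture(scope="session")
def drugs() -> dict:
    return dict(DRUGS)


@pytest.fixture(scope="session")
def toys() -> dict:
    return dict(TOY)


@pytest.fixture(scope="session")
def celecoxib() -> str:
    return DRUGS["celecoxib"]


def canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"fixture SMILES must parse: {smiles}"
    return Chem.MolToSmiles(mol)
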