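import logging

import pytest
from rdkit import Chem
from rdkit import RDLogger

from netscreen.chem import CompoundRecord, CompoundSet

RDLogger.DisableLog("rdApp.warning")
logging.getLogger("netscreen").setLevel(logging.ERROR)

# ten small molecules (<= 8 heavy atoms) for exhaustive-oracle comparisons
SMALL_MOLECULES = {
    "methane": "C",
    "ethane": "CC",
    "ethanol": "CCO",
    "propanol": "CCCO",
    "acetic_acid": "CC(=O)O",
    "propane": "CCC",
    "cyclopropane": "C1CC1",
    "butane": "CCCC",
    "benzene": "c1ccccc1",
    "isopropanol": "CC(C)O",
}


def record(cid: str, smiles: str) -> CompoundRecord:
    return CompoundRecord(compound_id=cid, name=cid,
                          mol=Chem.MolFromSmiles(smiles), source_format="smiles")


@pytest.fixture(scope="session")
def small_molecules() -> CompoundSet:
    return CompoundSet([record(cid, smi) for cid, smi in SMALL_MOLECULES.items()])


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One generated planted-structure bundle shared across tests."""
    from netscreen.fixtures import generate_fixtures

    out = tmp_path_factory.mktemp("bundle")
    return generate_fixtures(out, seed=42)
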