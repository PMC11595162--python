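"""Shared fixtures: toy complexes and small constructed molecules."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from posetriage.complex_io import LigandMolecule, assign_polar_hydrogens
from posetriage.synthetic_fixtures import FixtureSpec, make_toy_complex


def embedded_mol(smiles: str, name: str = "LIG", seed: int = 7) -> LigandMolecule:
    """A sanitized RDKit molecule with one MMFF-relaxed 3D conformer."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    return LigandMolecule(Chem.RemoveHs(mol), name=name)


def graph_mol(smiles: str, name: str = "LIG") -> LigandMolecule:
    """A molecule without coordinates (graph only)."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return LigandMolecule(mol, name=name)


@pytest.fixture(scope="session")
def cage_complex():
    """Enclosed toy pocket with polar hydrogens assigned."""
    return assign_polar_hydrogens(make_toy_complex(FixtureSpec(seed=1, geometry="cage")))


@pytest.fixture(scope="session")
def bowl_complex():
    """Open-surface toy pocket with polar hydrogens assigned."""
    return assign_polar_hydrogens(make_toy_complex(FixtureSpec(seed=1, geometry="bowl")))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
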