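"""Shared fixtures: tiny molecules, random graphs, one generated analog set."""

from __future__ import annotations

import numpy as np
import pytest

from tandemro import build_descriptor_matrix, generate_analog_set
from tandemro.molgraph import parse_smiles
from tandemro.synthdata import default_spec, random_molecule_graph

# small, chemically ordinary molecules used across the descriptor tests
SMILES_FIXTURES = {
    "ethane": "CC",
    "propane": "CCC",
    "ethanol": "CCO",
    "dimethyl_ether": "COC",
    "trimethylamine": "CN(C)C",
    "furan": "c1ccoc1",
    "formaldehyde": "C=O",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "chloromethane": "CCl",
    "acetic_acid": "CC(=O)O",
    "oxazole": "c1ocnc1",
    "isobutane": "CC(C)C",
    "neopentane": "CC(C)(C)C",
    "cyclohexane": "C1CCCCC1",
    "thiazolidinedione": "O=C1NC(=O)SC1",
    "rosiglitazone": "CN(CCOc1ccc(CC2SC(=O)NC2=O)cc1)c1ccccn1",
    "acetonitrile": "CC#N",
    "pyrrole": "c1cc[nH]c1",
}


@pytest.fixture(scope="session")
def mols():
    return {name: parse_smiles(smi, name=name) for name, smi in SMILES_FIXTURES.items()}


def random_graph(rng: np.random.Generator, max_atoms: int = 12):
    return random_molecule_graph(rng, max_atoms=max_atoms)


@pytest.fixture(scope="session")
def analog_set():
    """One default synthetic analog series (n=150, seed 0)."""
    return generate_analog_set(default_spec(seed=0))


@pytest.fixture(scope="session")
def analog_matrix(analog_set):
    return build_descriptor_matrix(analog_set.molecules)
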