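import numpy as np
import pytest

from mrensemble import (
    EnsembleSpec,
    build_consensus_set,
    make_helix_protein,
    make_solution_ensemble,
)
from mrensemble.structure import Atom, Structure


@pytest.fixture(scope="session")
def helix58():
    return make_helix_protein(58)


@pytest.fixture(scope="session")
def helix10():
    return make_helix_protein(10)


@pytest.fixture(scope="session")
def tight_ensemble(helix58):
    """Six near-identical 'final structure'-like models with rotamer flips
    of the surface glutamate at position 53."""
    spec = EnsembleSpec(
        n_models=6,
        backbone_noise_sigma=0.07,
        rotamer_plan={53: ["tt 0°", "tt 0°", "mm-40°", "mt-10°", "tt 0°", "mm-40°"]},
        seed=11,
    )
    return make_solution_ensemble(helix58, spec)


@pytest.fixture(scope="session")
def full_selection(tight_ensemble):
    return build_consensus_set(tight_ensemble)


def toy_structure(coords, residue_numbers=None, atom_names=None, label="toy", element="C"):
    """Bare structure from an (n, 3) array, one CA-like atom per residue by
    default."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if residue_numbers is None:
        residue_numbers = list(range(1, n + 1))
    if atom_names is None:
        atom_names = ["CA"] * n
    atoms = [
        Atom("A", residue_numbers[i], "ALA", atom_names[i], element, coords[i])
        for i in range(n)
    ]
    return Structure(atoms=atoms, label=label)


@pytest.fixture
def make_toy():
    return toy_structure
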