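"""Shared fixtures: toy receptors, ligands and parameter tables.

Everything is generated programmatically at session scope so the whole
suite runs from a clean checkout with no data files.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from selectiscreen.chem_io import AtomRecord, LigandMolecule, MolecularFormula, Receptor
from selectiscreen.fixtures import (
    FixtureSpec,
    LibrarySpec,
    make_decoy,
    make_planted_binder,
    make_receptor_pair,
)
from selectiscreen.params import default_parameters, default_tables


def toy_ligand(atom_types: list[str], coords, charges=None, name="toy") -> LigandMolecule:
    """Build a bare LigandMolecule with explicit types/coords (no chemistry).

    The backing RDKit mol is a disconnected carbon skeleton carrying one
    conformer; scoring only reads the AtomRecord list, so the toy can carry
    any type code the parameter tables know.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(atom_types)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    rw = Chem.RWMol()
    for _ in range(n):
        atom = Chem.Atom(6)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    mol = rw.GetMol()
    conf = Chem.Conformer(n)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.AddConformer(conf)
    atoms = [
        AtomRecord(serial=i, element=t.split(".")[0] if t not in ("HD",) else "H",
                   atom_type=t, coords=coords[i], partial_charge=float(charges[i]))
        for i, t in enumerate(atom_types)
    ]
    return LigandMolecule(name=name, rdkit_mol=mol, atoms=atoms, bonds=[],
                          n_tor=0, formula=MolecularFormula({"C": n}))


def toy_receptor(atom_types, coords, charges=None, resnum_start=700) -> Receptor:
    """Receptor of free-standing typed atoms, one residue per atom."""
    coords = np.asarray(coords, dtype=float)
    n = len(atom_types)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    atoms = []
    residue_index: dict[int, list[int]] = {}
    for i, t in enumerate(atom_types):
        element = "H" if t == "HD" else t.split(".")[0]
        resnum = resnum_start + i
        atoms.append(
            AtomRecord(serial=i, element=element, atom_type=t, coords=coords[i],
                       partial_charge=float(charges[i]), name=element,
                       residue=("TOY", resnum, "A"), is_backbone=False,
                       is_receptor=True)
        )
        residue_index[resnum] = [i]
    return Receptor(atoms=atoms, residue_index=residue_index,
                    hinge_residues=frozenset(), name="toy")


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def receptor_pair(fixture_spec):
    return make_receptor_pair(fixture_spec)


@pytest.fixture(scope="session")
def planted(fixture_spec, receptor_pair):
    mut, _ = receptor_pair
    return make_planted_binder(mut, fixture_spec)


@pytest.fixture(scope="session")
def decoy(fixture_spec):
    return make_decoy(fixture_spec)


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def small_library_spec() -> FixtureSpec:
    return FixtureSpec(
        seed=13,
        library=LibrarySpec(n_in_window=10, n_below=3, n_above=2,
                            n_planted_clusters=1, cluster_size=4),
    )


def prepared_ligand(smiles: str, seed: int = 99) -> LigandMolecule:
    from selectiscreen.chem_io import ligand_from_smiles

    return ligand_from_smiles(smiles, seed=seed)
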