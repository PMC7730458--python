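"""Structure I/O, typing, charges, rotatable bonds and formula machinery."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from selectiscreen.chem_io import (
    ChemIOError,
    MolecularFormula,
    assign_gasteiger_charges,
    count_rotatable_bonds,
    ligand_from_smiles,
    monoisotopic_mass,
    parse_formula,
    read_ligands,
    read_receptor,
    ro5_profile,
    write_ligands,
    write_receptor,
)


# ---------------------------------------------------------------------------
# formulas and masses
# ---------------------------------------------------------------------------

class TestFormula:
    def test_parse_simple(self):
        f = parse_formula("H2O")
        assert f.counts == {"H": 2, "O": 1}

    def test_parse_multi_element(self):
        f = parse_formula("C23H21NO4")
        assert f.counts == {"C": 23, "H": 21, "N": 1, "O": 4}

    def test_zero_count_rejected(self):
        with pytest.raises(ChemIOError):
            parse_formula("C0H2")

    def test_unknown_element_rejected(self):
        with pytest.raises(ChemIOError):
            parse_formula("Xx2O")

    def test_hill_round_trip(self):
        for text in ("C23H21NO4", "H2O", "C6H12O6", "C2H6OS"):
            assert parse_formula(text).hill() == text

    def test_charge_suffix(self):
        f = parse_formula("C23H21NO4+")
        assert f.net_charge == 1
        assert f.counts["C"] == 23

    def test_diatomic_hydrogen_mass(self):
        assert monoisotopic_mass("H2") == pytest.approx(2 * 1.00782503, abs=1e-4)

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Cl"]),
            st.integers(min_value=1, max_value=40),
            min_size=1,
        ),
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Cl"]),
            st.integers(min_value=1, max_value=40),
            min_size=1,
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, counts_a, counts_b):
        """Monoisotopic mass is exactly additive over formula union."""
        a, b = MolecularFormula(counts_a), MolecularFormula(counts_b)
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )


# ---------------------------------------------------------------------------
# Gasteiger charges
# ---------------------------------------------------------------------------

def _gasteiger_oracle_water(n_iter: int = 12) -> list[float]:
    """Independent implementation of the published PEOE iteration for water.

    Electronegativity chi = a + b*q + c*q^2 with the original orbital
    parameters (O sp3: 14.18/12.92/1.39; H: 7.17/6.24/-0.56); the charge
    transferred across a bond per cycle is damped by (1/2)^k, and the
    normalizing denominator is the cation electronegativity of the less
    electronegative atom (20.02 for hydrogen).
    """
    par = {"O": (14.18, 12.92, 1.39), "H": (7.17, 6.24, -0.56)}
    elems = ["O", "H", "H"]
    bonds = [(0, 1), (0, 2)]
    q = [0.0, 0.0, 0.0]
    for k in range(1, n_iter + 1):
        chi = [par[e][0] + par[e][1] * qi + par[e][2] * qi * qi
               for e, qi in zip(elems, q)]
        dq = [0.0, 0.0, 0.0]
        for i, j in bonds:
            if chi[j] > chi[i]:
                lo = elems[i]
            else:
                lo = elems[j]
            denom = 20.02 if lo == "H" else sum(par[lo])
            t = (chi[j] - chi[i]) / denom * 0.5**k
            dq[i] += t
            dq[j] -= t
        q = [qi + d for qi, d in zip(q, dq)]
    return q


class TestGasteiger:
    def test_methane_symmetry(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("C"))
        assign_gasteiger_charges(mol)
        charges = [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
        h = charges[1:]
        assert max(h) - min(h) < 1e-12
        assert sum(charges) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "smiles", ["O", "CCO", "c1ccccc1", "CC(=O)O", "CN", "C(F)(F)F", "CS"]
    )
    def test_charge_conservation(self, smiles):
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        assign_gasteiger_charges(mol)
        total = sum(a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms())
        assert total == pytest.approx(Chem.GetFormalCharge(mol), abs=1e-6)

    def test_water_matches_independent_iteration(self):
        """Charges on water agree with a from-scratch PEOE oracle to 1e-3 e."""
        mol = Chem.AddHs(Chem.MolFromSmiles("O"))
        assign_gasteiger_charges(mol)
        got = [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
        expected = _gasteiger_oracle_water()
        assert got == pytest.approx(expected, abs=1e-3)
        assert got[0] < 0 < got[1]


# ---------------------------------------------------------------------------
# rotatable bonds
# ---------------------------------------------------------------------------

def _rotor_oracle(mol: Chem.Mol) -> int:
    """Exhaustive bond classification against the stated definition."""
    n = 0
    amide = {frozenset((m[0], m[2]))
             for m in mol.GetSubstructMatches(Chem.MolFromSmarts("C(=O)N"))}
    for b in mol.GetBonds():
        if b.GetBondTypeAsDouble() != 1.0 or b.IsInRing():
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if min(a1.GetAtomicNum(), a2.GetAtomicNum()) == 1:
            continue
        heavy = lambda a: sum(nb.GetAtomicNum() > 1 for nb in a.GetNeighbors())
        if heavy(a1) < 2 or heavy(a2) < 2:
            continue
        if frozenset((a1.GetIdx(), a2.GetIdx())) in amide:
            continue
        n += 1
    return n


class TestRotatableBonds:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CC", 0),  # ethane: both carbons terminal
            ("CCCC", 1),  # n-butane: the single central bond
            ("c1ccccc1-c1ccccc1", 1),  # biphenyl: the inter-ring bond
            ("CC(=O)NC", 0),  # amide C-N excluded; both methyls terminal
            ("CCOCC", 2),
            ("C1CCCCC1", 0),  # ring bonds never count
        ],
    )
    def test_known_counts(self, smiles, expected):
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        assert count_rotatable_bonds(mol) == expected

    @pytest.mark.parametrize(
        "smiles",
        [
            "CCO", "CCCCCC", "c1ccccc1CCN", "CC(=O)Nc1ccccc1", "COc1ccccc1OC",
            "CC(C)CC(=O)O", "c1ccc2ccccc2c1", "O=S(=O)(N)c1ccccc1",
            "CCOC(=O)c1ccccc1", "NC(=O)CCC(=O)O", "CN(C)CCCl", "C#CCO",
            "c1ccncc1CCO", "CSCC(N)C(=O)O", "OCC(O)C(O)CO", "FC(F)(F)c1ccccc1",
            "CC(C)(C)OC(=O)N", "c1ccc(-c2ccco2)cc1", "BrCCCCBr", "CNC(=O)NC",
        ],
    )
    def test_agrees_with_enumeration_oracle(self, smiles):
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        assert count_rotatable_bonds(mol) == _rotor_oracle(mol)


# ---------------------------------------------------------------------------
# rule-of-five profiles
# ---------------------------------------------------------------------------

class TestRo5:
    def test_benzene(self):
        p = ro5_profile(Chem.MolFromSmiles("c1ccccc1"))
        assert (p.hbd, p.hba, p.violations) == (0, 0, 0)

    def test_glucose(self):
        p = ro5_profile(Chem.MolFromSmiles("OCC1OC(O)C(O)C(O)C1O"))
        assert (p.hbd, p.hba, p.violations) == (5, 6, 0)

    def test_heavy_greasy_molecule_violates_twice(self):
        smiles = "CCCCCCCCCCCCCCCCCCCCCCc1ccc(CCCCCCCCCCCC)cc1"
        p = ro5_profile(Chem.MolFromSmiles(smiles))
        assert p.mw > 500 and p.logp > 5
        assert p.violations >= 2


# ---------------------------------------------------------------------------
# ligand reading / writing
# ---------------------------------------------------------------------------

class TestLigandIO:
    def test_smiles_benzene_explicit_h(self, tmp_path):
        path = tmp_path / "lib.smi"
        path.write_text("c1ccccc1 benzene\n")
        mols = read_ligands(path)
        assert len(mols) == 1
        assert len(mols[0].atoms) == 12
        assert mols[0].rdkit_mol.GetNumConformers() == 1

    def test_bad_entries_skipped_not_fatal(self, tmp_path, caplog):
        path = tmp_path / "lib.smi"
        path.write_text("c1ccccc1 ok\nnot_a_smiles xx\nCCO ok2\n")
        mols = read_ligands(path)
        assert [m.name for m in mols] == ["ok", "ok2"]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.smi"
        path.write_text("")
        assert read_ligands(path) == []

    def test_sdf_round_trip_preserves_topology(self, tmp_path):
        originals = [ligand_from_smiles(s, seed=5)
                     for s in ("CCO", "c1ccccc1C(=O)NC", "CC(C)CC")]
        path = tmp_path / "out.sdf"
        write_ligands(originals, path)
        back = read_ligands(path)
        assert len(back) == len(originals)
        for a, b in zip(originals, back):
            assert len(a.atoms) == len(b.atoms)
            assert len(a.bonds) == len(b.bonds)
            assert a.n_tor == b.n_tor

    def test_sdf_with_invalid_record(self, tmp_path):
        good = [ligand_from_smiles("CCO", seed=5), ligand_from_smiles("CCN", seed=5)]
        path = tmp_path / "mixed.sdf"
        write_ligands(good, path)
        text = path.read_text()
        # splice in a corrupt record between the two molecules
        parts = text.split("$$$$\n")
        corrupt = "broken\n  header\n\n  3  99  0\njunk\nM  END\n"
        path.write_text(parts[0] + "$$$$\n" + corrupt + "$$$$\n" + parts[1] + "$$$$\n")
        mols = read_ligands(path)
        assert len(mols) == 2


# ---------------------------------------------------------------------------
# receptor reading
# ---------------------------------------------------------------------------

class TestReceptorIO:
    def test_round_trip_toy_receptor(self, tmp_path, receptor_pair):
        mut, _ = receptor_pair
        path = tmp_path / "mut.pdb"
        write_receptor(mut, path)
        back = read_receptor(path)
        assert len(back.atoms) == len(mut.atoms)
        assert set(back.residue_index) == set(mut.residue_index)
        back.require_hinge()
        for a, b in zip(mut.atoms, back.atoms):
            assert a.element == b.element
            assert b.partial_charge == pytest.approx(a.partial_charge, abs=0.005)
            assert np.allclose(a.coords, b.coords, atol=1e-3)

    def test_three_residue_count(self, tmp_path):
        lines = []
        for k, res in enumerate(("ALA", "GLY", "SER"), start=1):
            lines.append(
                f"ATOM  {k:5d}  CA  {res} A{k:4d}    "
                f"{k * 1.0:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           C"
            )
        path = tmp_path / "toy.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        rec = read_receptor(path)
        assert len(rec.residue_index) == 3

    def test_truncated_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      1.0\n")
        with pytest.raises(ChemIOError, match=r":1:"):
            read_receptor(path)

    def test_waters_excluded_by_default(self, tmp_path, receptor_pair):
        mut, _ = receptor_pair
        path = tmp_path / "wet.pdb"
        write_receptor(mut, path)
        water = (
            f"HETATM 9999  O   HOH A 999    {50.0:8.3f}{50.0:8.3f}{50.0:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}           O"
        )
        text = path.read_text().replace("END", water + "\nEND")
        path.write_text(text)
        rec = read_receptor(path)
        assert 999 not in rec.residue_index
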