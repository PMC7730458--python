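"""Molecular structure I/O, atom typing, charges, and formula machinery.

Everything downstream of this module (scoring, grids, screening) consumes the
containers defined here: :class:`AtomRecord`, :class:`LigandMolecule`,
:class:`Receptor` and :class:`MolecularFormula`.  Ligands are backed by RDKit
molecules with explicit hydrogens and a single 3D conformer; receptors are
read from PDB files with gemmi.

Conventions
-----------
* Coordinates are in Angstrom, right-handed, taken verbatim from the input.
* Partial charges are in units of the elementary charge.  PDB has no charge
  column, so receptor PDB files written by this package store the partial
  charge in the B-factor column (the same trick PDBQT plays with an extra
  column); :func:`read_receptor` reads it back from there by default.
* Residue numbers are kept verbatim (1-based mature-protein numbering for
  EGFR-like receptors, where the kinase domain spans residues ~700-1014 and
  the hinge is 791-795).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Bond",
    "LigandMolecule",
    "Receptor",
    "MolecularFormula",
    "Ro5Profile",
    "ChemIOError",
    "read_receptor",
    "write_receptor",
    "read_ligands",
    "write_ligands",
    "ligand_from_smiles",
    "ligand_from_rdkit",
    "assign_gasteiger_charges",
    "count_rotatable_bonds",
    "parse_formula",
    "monoisotopic_mass",
    "ro5_profile",
    "ATOM_TYPES",
]


class ChemIOError(ValueError):
    """Raised for malformed structures, unknown elements or missing parameters."""


# Finite atom-typing scheme.  The scoring tables are keyed on these codes.
ATOM_TYPES = ("C", "C.ar", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H", "HD")

_POLAR_H_NEIGHBORS = {"N", "O", "S"}
_HETERO_BY_ELEMENT = {"N": "N", "O": "O", "S": "S", "P": "P",
                      "F": "F", "Cl": "Cl", "Br": "Br", "I": "I"}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT"}


@dataclass(frozen=True)
class AtomRecord:
    """One typed, charged atom.

    ``partial_charge`` is the q_i entering the electrostatic term; the
    ``atom_type`` code keys the pair-potential and hydration tables (which
    supply S_i, V_i and O_i^max for the dehydration term).
    """

    serial: int
    element: str
    atom_type: str
    coords: np.ndarray
    partial_charge: float
    name: str = ""
    residue: tuple[str, int, str] | None = None  # (resname, resseq, chain)
    is_backbone: bool = False
    is_receptor: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ChemIOError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if abs(self.partial_charge) >= 2.0:
            raise ChemIOError(
                f"atom {self.serial}: |partial charge| {self.partial_charge:+.3f} e "
                "is out of range for an organic atom"
            )
        if self.is_receptor != (self.residue is not None):
            raise ChemIOError(f"atom {self.serial}: residue info present iff receptor atom")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float
    in_ring: bool


@dataclass
class MolecularFormula:
    """Element-count map with a canonical Hill-order rendering."""

    counts: dict[str, int]
    net_charge: int = 0

    def __post_init__(self) -> None:
        pt = Chem.GetPeriodicTable()
        for element, count in self.counts.items():
            if not isinstance(count, int) or count <= 0:
                raise ChemIOError(f"formula count for {element} must be a positive integer")
            try:
                known = pt.GetAtomicNumber(element) > 0
            except RuntimeError:
                known = False
            if not known:
                raise ChemIOError(f"unknown element symbol: {element!r}")

    def hill(self) -> str:
        """Canonical Hill notation: C, H, then other elements alphabetically."""
        parts: list[str] = []
        rest = dict(self.counts)
        for element in ("C", "H"):
            if "C" in self.counts and element in rest:
                n = rest.pop(element)
                parts.append(element + (str(n) if n > 1 else ""))
        for element in sorted(rest):
            n = rest[element]
            parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            counts[element] = counts.get(element, 0) + n
        return MolecularFormula(counts, self.net_charge + other.net_charge)


@dataclass(frozen=True)
class Ro5Profile:
    mw: float
    logp: float
    hbd: int
    hba: int
    violations: int


@dataclass
class LigandMolecule:
    """A small molecule with explicit hydrogens, one 3D conformer, charges and types."""

    name: str
    rdkit_mol: Chem.Mol
    atoms: list[AtomRecord]
    bonds: list[Bond]
    n_tor: int
    formula: MolecularFormula

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.rdkit_mol))

    def with_coords(self, coords: np.ndarray) -> "LigandMolecule":
        """Copy of the molecule with atom coordinates replaced (topology shared)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ChemIOError("coordinate array shape mismatch")
        atoms = [replace(a, coords=coords[i]) for i, a in enumerate(self.atoms)]
        mol = Chem.Mol(self.rdkit_mol)
        conf = mol.GetConformer()
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
        return LigandMolecule(self.name, mol, atoms, self.bonds, self.n_tor, self.formula)

    def donor_heavy_of_hydrogen(self) -> dict[int, int]:
        """Map polar-hydrogen atom index -> its bonded heavy (donor) atom index."""
        out: dict[int, int] = {}
        for b in self.bonds:
            for h, d in ((b.i, b.j), (b.j, b.i)):
                if self.atoms[h].atom_type == "HD":
                    out[h] = d
        return out


@dataclass
class Receptor:
    """Protein (or toy pocket) as residue-indexed typed atoms."""

    atoms: list[AtomRecord]
    residue_index: dict[int, list[int]] = field(default_factory=dict)
    hinge_residues: frozenset[int] = frozenset(range(791, 796))
    pocket_center: np.ndarray | None = None
    name: str = "receptor"

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    def require_hinge(self) -> None:
        missing = sorted(r for r in self.hinge_residues if r not in self.residue_index)
        if missing:
            raise ChemIOError(f"hinge residues missing from receptor: {missing}")

    def donor_heavy_of_hydrogen(self, max_bond: float = 1.3) -> dict[int, int]:
        """Polar hydrogen -> donor heavy atom, resolved by distance (PDB has no bonds)."""
        out: dict[int, int] = {}
        coords = self.coords
        heavy = [i for i, a in enumerate(self.atoms) if a.element in _POLAR_H_NEIGHBORS]
        if not heavy:
            return out
        heavy_xyz = coords[heavy]
        for i, a in enumerate(self.atoms):
            if a.atom_type != "HD":
                continue
            d = np.linalg.norm(heavy_xyz - coords[i], axis=1)
            out[i] = heavy[int(np.argmin(d))]
        return out


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

def _type_rdkit_atom(atom: Chem.Atom) -> str:
    symbol = atom.GetSymbol()
    if symbol == "C":
        return "C.ar" if atom.GetIsAromatic() else "C"
    if symbol == "H":
        for nb in atom.GetNeighbors():
            if nb.GetSymbol() in _POLAR_H_NEIGHBORS:
                return "HD"
        return "H"
    try:
        return _HETERO_BY_ELEMENT[symbol]
    except KeyError:
        raise ChemIOError(f"no atom-typing rule for element {symbol!r}") from None


def _type_receptor_atom(element: str, neighbors_polar: bool) -> str:
    if element == "C":
        return "C"
    if element == "H":
        return "HD" if neighbors_polar else "H"
    try:
        return _HETERO_BY_ELEMENT[element]
    except KeyError:
        raise ChemIOError(f"no atom-typing rule for element {element!r}") from None


# ---------------------------------------------------------------------------
# ligands
# ---------------------------------------------------------------------------

def assign_gasteiger_charges(mol: Chem.Mol, n_iter: int = 12) -> Chem.Mol:
    """Assign Gasteiger-Marsili partial charges (PEOE) in place and return the mol.

    The iteration damps charge transfer by 1/2^k per cycle, so twelve cycles
    are far past convergence for organic molecules.  The sum of the charges
    equals the net formal charge to numerical precision.
    """
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ("C", "H", *_HETERO_BY_ELEMENT):
            raise ChemIOError(
                f"no electronegativity parameters for element {atom.GetSymbol()!r}"
            )
    AllChem.ComputeGasteigerCharges(mol, nIter=n_iter, throwOnParamFailure=True)
    return mol


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Number of rotatable bonds, the N_tor entropic-penalty count.

    Definition: an acyclic single bond between two heavy atoms that each have
    at least two heavy-atom neighbours, excluding amide C-N bonds.  Terminal
    groups (-CH3, -NH2, -OH, halogens) therefore never contribute.
    """
    amide = mol.GetSubstructMatches(Chem.MolFromSmarts("[CX3](=[OX1])[NX3]"))
    amide_cn = {frozenset((m[0], m[2])) for m in amide}
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        if _heavy_degree(a) < 2 or _heavy_degree(b) < 2:
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_cn:
            continue
        n += 1
    return n


def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)


def _formula_of_rdkit(mol: Chem.Mol) -> MolecularFormula:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return MolecularFormula(counts, Chem.GetFormalCharge(mol))


def ligand_from_rdkit(
    mol: Chem.Mol, name: str = "", seed: int = 2023, embed: bool = True
) -> LigandMolecule:
    """Promote an RDKit mol to a fully prepared :class:`LigandMolecule`.

    Adds explicit hydrogens, embeds a 3D conformer with seeded ETKDG when the
    molecule has none (reproducible for a fixed seed), assigns
    Gasteiger-Marsili charges and atom types, counts rotatable bonds and
    derives the molecular formula.
    """
    mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
    if mol.GetNumConformers() == 0:
        if not embed:
            raise ChemIOError(f"molecule {name!r} has no conformer and embedding is off")
        params = AllChem.ETKDGv3()
        params.randomSeed = seed % (2**31 - 1)
        if AllChem.EmbedMolecule(mol, params) != 0:
            params.useRandomCoords = True
            if AllChem.EmbedMolecule(mol, params) != 0:
                raise ChemIOError(f"3D embedding failed for molecule {name!r}")
        AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    assign_gasteiger_charges(mol)
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        if not math.isfinite(q):
            raise ChemIOError(f"non-finite Gasteiger charge on atom {atom.GetIdx()}")
        atoms.append(
            AtomRecord(
                serial=atom.GetIdx(),
                element=atom.GetSymbol(),
                atom_type=_type_rdkit_atom(atom),
                coords=np.array([pos.x, pos.y, pos.z]),
                partial_charge=q,
            )
        )
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(), b.IsInRing())
        for b in mol.GetBonds()
    ]
    return LigandMolecule(
        name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
        rdkit_mol=mol,
        atoms=atoms,
        bonds=bonds,
        n_tor=count_rotatable_bonds(mol),
        formula=_formula_of_rdkit(mol),
    )


def ligand_from_smiles(smiles: str, name: str = "", seed: int = 2023) -> LigandMolecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemIOError(f"unparsable SMILES: {smiles!r}")
    return ligand_from_rdkit(mol, name=name or smiles, seed=seed)


def read_ligands(path: str | Path, seed: int = 2023) -> list[LigandMolecule]:
    """Read an SDF or SMILES library into prepared ligands.

    Unparsable entries are skipped with a logged warning; they never abort
    the batch.  For SMILES input the format is one molecule per line,
    optionally followed by a whitespace-separated id.
    """
    path = Path(path)
    out: list[LigandMolecule] = []
    n_bad = 0
    if path.suffix.lower() in (".smi", ".smiles", ".txt", ".ism"):
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
            try:
                out.append(ligand_from_smiles(smiles, name=name, seed=seed + ln))
            except ChemIOError as exc:
                n_bad += 1
                log.warning("skipping line %d of %s: %s", ln, path, exc)
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for k, mol in enumerate(supplier):
            if mol is None:
                n_bad += 1
                log.warning("skipping unreadable record %d of %s", k + 1, path)
                continue
            try:
                out.append(ligand_from_rdkit(mol, seed=seed + k))
            except ChemIOError as exc:
                n_bad += 1
                log.warning("skipping record %d of %s: %s", k + 1, path, exc)
    if n_bad:
        log.warning("%d entries skipped while reading %s", n_bad, path)
    return out


def write_ligands(mols: Iterable[LigandMolecule], path: str | Path) -> None:
    """Write ligands (with conformers and any pose metadata props) to SDF."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for m in mols:
        rm = Chem.Mol(m.rdkit_mol)
        rm.SetProp("_Name", m.name)
        writer.write(rm)
    writer.close()


# ---------------------------------------------------------------------------
# receptors
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str, path: Path) -> None:
    for ln, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ChemIOError(f"{path}:{ln}: truncated coordinate record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise ChemIOError(f"{path}:{ln}: malformed coordinates") from None


def read_receptor(
    path: str | Path,
    keep_hetero: bool = False,
    charges: str = "bfactor",
    hinge_residues: Iterable[int] = range(791, 796),
) -> Receptor:
    """Read a PDB receptor.

    Waters and other heteroatoms are excluded unless ``keep_hetero``.
    ``charges`` is ``"bfactor"`` (partial charges stored in the B-factor
    column, the convention used by :func:`write_receptor`) or ``"zero"``.
    """
    import gemmi

    path = Path(path)
    text = path.read_text()
    _validate_pdb_lines(text, path)
    structure = gemmi.read_pdb_string(text)
    structure.setup_entities()
    atoms: list[AtomRecord] = []
    residue_index: dict[int, list[int]] = {}
    serial = 0
    model = structure[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if het and (not keep_hetero or res.name == "HOH"):
                continue
            polar_here = any(a.element.name in _POLAR_H_NEIGHBORS for a in res)
            for a in res:
                element = a.element.name
                q = float(a.b_iso) if charges == "bfactor" else 0.0
                atom_type = _type_receptor_atom(element, polar_here)
                rec = AtomRecord(
                    serial=serial,
                    element=element,
                    atom_type=atom_type,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    partial_charge=q,
                    name=a.name,
                    residue=(res.name, res.seqid.num, chain.name or ""),
                    is_backbone=a.name in _BACKBONE_NAMES,
                    is_receptor=True,
                )
                residue_index.setdefault(res.seqid.num, []).append(serial)
                atoms.append(rec)
                serial += 1
    return Receptor(
        atoms=atoms,
        residue_index=residue_index,
        hinge_residues=frozenset(hinge_residues),
        name=path.stem,
    )


def write_receptor(receptor: Receptor, path: str | Path) -> None:
    """Write a receptor as PDB, storing partial charges in the B-factor column."""
    lines = []
    for k, a in enumerate(receptor.atoms, start=1):
        resname, resseq, chain = a.residue or ("UNK", 1, "A")
        x, y, z = a.coords
        name = a.name or a.element
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"ATOM  {k:5d} {name_field}"
            f" {resname:<3s} {chain or 'A':1s}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{a.partial_charge:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# formulas and properties
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula like ``C23H21NO4`` (optional trailing +/-)."""
    text = text.strip()
    net_charge = 0
    m = re.search(r"([+-]\d*)$", text)
    if m and m.group(0):
        tok = m.group(0)
        sign = -1 if tok[0] == "-" else 1
        digits = tok[1:]
        net_charge = sign * (int(digits) if digits else 1)
        text = text[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ChemIOError(f"cannot parse formula at {text[pos:]!r}")
        pos = m.end()
        element = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        if n == 0:
            raise ChemIOError(f"zero count for element {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text) or not counts:
        raise ChemIOError(f"cannot parse formula {text!r}")
    return MolecularFormula(counts, net_charge)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic mass (Da) of the neutral formula.

    Sum of principal-isotope masses; no electron-mass correction is applied,
    matching the convention of EI-HRMS "calcd." values for radical cations.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    pt = Chem.GetPeriodicTable()
    total = 0.0
    for element, n in formula.counts.items():
        m = pt.GetMostCommonIsotopeMass(element)
        if m <= 0:
            raise ChemIOError(f"no principal-isotope mass for element {element!r}")
        total += n * m
    return total


def average_mass(formula: MolecularFormula | str) -> float:
    """Average (isotope-abundance-weighted) molecular weight in amu."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    pt = Chem.GetPeriodicTable()
    return sum(n * pt.GetAtomicWeight(el) for el, n in formula.counts.items())


def ro5_profile(mol: Chem.Mol | LigandMolecule) -> Ro5Profile:
    """Lipinski rule-of-five profile.

    MW uses average atomic masses; logP is the Crippen atom-contribution
    estimate; donors are N/O bearing at least one hydrogen; acceptors are the
    N+O count.  A molecule is conventionally called compliant when it has at
    most one violation.
    """
    rdmol = mol.rdkit_mol if isinstance(mol, LigandMolecule) else mol
    mw = Descriptors.MolWt(rdmol)
    logp = Crippen.MolLogP(rdmol)
    hbd = Lipinski.NHOHCount(rdmol)
    hba = Lipinski.NOCount(rdmol)
    violations = sum([mw > 500.0, logp > 5.0, hbd > 5, hba > 10])
    return Ro5Profile(mw=mw, logp=logp, hbd=hbd, hba=hba, violations=violations)
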