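"""Deterministic synthetic fixtures: receptors, binders and compound libraries.

Real kinase structures are optional inputs to this package; every pipeline
stage is exercisable on the fixtures built here, which are pure functions of
a :class:`FixtureSpec` (same seed, byte-identical output).

The toy receptor is an abstract typed-atom pocket, not a protein: a
five-residue *hinge mimic* (numbered 791-795, each with backbone N, H, CA,
C, O so the bidentate hydrogen-bond filter has real donors and acceptors)
plus a shell of carbon "lining" atoms around a pocket center.  The
mutant/wild-type pair differs at exactly two designated lining atoms,
mimicking gatekeeper-style swaps: residue 790 polar(O)→nonpolar(S) and
residue 797 thiol(S)→hydroxyl(O).

The library generator assembles drug-like molecules from a curated
scaffold/substituent set and records a ground-truth table (MW, rule-of-five
violations, cluster id), so the survivor count of every filtration stage is
known in advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import AtomRecord, LigandMolecule, Receptor, ligand_from_smiles
from .denovo import attach_fragment
from .screen import LibraryEntry, cluster_by_tanimoto, make_library_entry, ro5_filter, mw_window_filter

__all__ = [
    "LibrarySpec",
    "FixtureSpec",
    "make_receptor_pair",
    "make_library",
    "make_planted_binder",
    "make_decoy",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of the synthetic screening library."""

    n_in_window: int = 170  # molecules with MW in [300, 400] amu
    n_below: int = 15  # MW < 300
    n_above: int = 15  # MW > 400
    n_planted_clusters: int = 3  # near-duplicate families planted in-window
    cluster_size: int = 4

    @property
    def n_total(self) -> int:
        return self.n_in_window + self.n_below + self.n_above


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 7
    n_lining: int = 14  # pocket-lining carbon atoms
    pocket_radius: float = 6.0  # Å, lining shell radius around the pocket center
    mutate: bool = True  # emit a mutant/wild-type pair differing at 2 atoms
    library: LibrarySpec = field(default_factory=LibrarySpec)


# ---------------------------------------------------------------------------
# receptors
# ---------------------------------------------------------------------------

_HINGE_X0 = 0.0
_HINGE_DX = 3.8  # Å between consecutive hinge residues


def _hinge_atoms(start_serial: int) -> list[AtomRecord]:
    """Five hinge-mimic residues with backbone N-H and C=O pointing at the pocket."""
    atoms: list[AtomRecord] = []
    serial = start_serial
    for k, resnum in enumerate(range(791, 796)):
        x = _HINGE_X0 + k * _HINGE_DX
        res = ("HNG", resnum, "A")
        # alternate the amide orientation as real hinge strands do: even
        # residues present N-H and C=O to the pocket (+y), odd ones face away
        flip = 1.0 if k % 2 == 0 else -1.0
        o_y = 0.73 if flip > 0 else -1.73
        spec = [
            ("N", "N", "N", np.array([x, 0.0, 0.0]), -0.35, True),
            ("H", "H", "HD", np.array([x, 1.01 * flip, 0.0]), 0.25, True),
            ("CA", "C", "C", np.array([x + 1.2, -1.0, 0.0]), 0.05, True),
            ("C", "C", "C", np.array([x + 2.4, -0.5, 0.0]), 0.45, True),
            ("O", "O", "O", np.array([x + 2.4, o_y, 0.0]), -0.45, True),
        ]
        for name, element, atype, xyz, q, backbone in spec:
            atoms.append(
                AtomRecord(
                    serial=serial, element=element, atom_type=atype, coords=xyz,
                    partial_charge=q, name=name, residue=res,
                    is_backbone=backbone, is_receptor=True,
                )
            )
            serial += 1
    return atoms


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    return np.stack([r * np.cos(phi * k), y, r * np.sin(phi * k)], axis=1)


# anchor targets of the planted binder (see make_planted_binder)
_POCKET_CENTER = np.array([5.2, 3.6, 0.6])


def make_receptor_pair(spec: FixtureSpec) -> tuple[Receptor, Receptor]:
    """Build the (mutant, wild-type) toy receptor pair.

    With ``spec.mutate`` off the two receptors are atom-for-atom identical;
    with it on they differ at exactly the two designated "mutation" atoms
    (residues 790 and 797) in atom type, element and charge only.
    """
    hinge = _hinge_atoms(0)
    serial = len(hinge)
    center = _POCKET_CENTER

    # The lining shell is a complementary "glove": carbon atoms placed on an
    # offset surface of the planted binder at the van der Waals optimum, so
    # the planted pose sits in a snug attractive pocket and any displaced
    # pose runs into the repulsive wall.  Deterministic: fixed direction set,
    # fixed iteration order, no randomness.
    planted_xyz = _planted_coords(hinge, spec.seed)
    hinge_xyz = np.array([a.coords for a in hinge])
    contact = 3.95  # Å, near the C-C 12-6 minimum of the default pair table

    directions = _fibonacci_sphere(26)
    lining_pos: list[np.ndarray] = []
    heavy = [i for i in range(len(planted_xyz))]
    for d in directions:
        for i in heavy:
            p = planted_xyz[i] + contact * d
            if np.min(np.linalg.norm(planted_xyz - p, axis=1)) < contact - 0.15:
                continue  # would clash with another ligand atom
            if np.min(np.linalg.norm(hinge_xyz - p, axis=1)) < 3.2:
                continue  # keep the hinge face open
            if lining_pos and np.min(
                np.linalg.norm(np.array(lining_pos) - p, axis=1)
            ) < 3.0:
                continue  # keep the shell itself sparse
            lining_pos.append(p)
            break
        if len(lining_pos) == spec.n_lining:
            break
    if len(lining_pos) < spec.n_lining:
        raise ValueError(
            f"could only place {len(lining_pos)} of {spec.n_lining} lining atoms"
        )

    def _lining_atoms(variant: str) -> list[AtomRecord]:
        atoms: list[AtomRecord] = []
        s = serial
        for k, p in enumerate(lining_pos):
            if spec.mutate and k == 0:
                resnum, resname = 790, "GKP"  # gatekeeper-style site
                if variant == "wt":
                    element, atype, q = "O", "O", -0.40  # threonine-like hydroxyl O
                else:
                    element, atype, q = "S", "S", -0.10  # methionine-like S
                name = element
            elif spec.mutate and k == 1:
                resnum, resname = 797, "CSS"  # thiol→hydroxyl site
                if variant == "wt":
                    element, atype, q = "S", "S", -0.20  # cysteine-like thiol S
                else:
                    element, atype, q = "O", "O", -0.40  # serine-like hydroxyl O
                name = element
            else:
                resnum, resname = 718 + k, "POC"
                element, atype, q, name = "C", "C", 0.0, "C1"
            atoms.append(
                AtomRecord(
                    serial=s, element=element, atom_type=atype, coords=p.copy(),
                    partial_charge=q, name=name, residue=(resname, resnum, "A"),
                    is_backbone=False, is_receptor=True,
                )
            )
            s += 1
        return atoms

    def _assemble(variant: str) -> Receptor:
        atoms = [*hinge, *_lining_atoms(variant)]
        residue_index: dict[int, list[int]] = {}
        for a in atoms:
            residue_index.setdefault(a.residue[1], []).append(a.serial)
        return Receptor(
            atoms=atoms,
            residue_index=residue_index,
            hinge_residues=frozenset(range(791, 796)),
            pocket_center=center.copy(),
            name=f"toy-{variant}",
        )

    return _assemble("mut"), _assemble("wt")


# ---------------------------------------------------------------------------
# planted binder and decoy
# ---------------------------------------------------------------------------

_PLANTED_SMILES = "Oc1ccc2ncccc2c1"  # 6-hydroxyquinoline: ring-N acceptor, phenol donor


def _planted_coords(hinge_atoms: list[AtomRecord], seed: int) -> np.ndarray:
    """Planted-binder coordinates, a pure function of the hinge and seed.

    The pyridine nitrogen (acceptor) is anchored in front of the backbone
    N-H of residue 793 and the phenolic oxygen (donor) in front of the
    carbonyl O of residue 791, both inside the 3.5 Å heavy-atom criterion;
    the rigid fit is a three-anchor Kabsch alignment.
    """
    from scipy.spatial.transform import Rotation

    mol = ligand_from_smiles(_PLANTED_SMILES, name="planted_binder", seed=seed)
    rd = mol.rdkit_mol
    n_idx = next(a.GetIdx() for a in rd.GetAtoms() if a.GetSymbol() == "N")
    o_idx = next(a.GetIdx() for a in rd.GetAtoms() if a.GetSymbol() == "O")

    by_res = {}
    for a in hinge_atoms:
        by_res.setdefault(a.residue[1], {})[a.name] = a.coords
    target_n = by_res[793]["N"] + np.array([0.0, 3.00, 0.6])
    target_o = by_res[791]["O"] + np.array([0.0, 3.00, 0.6])

    coords = mol.coords
    src = np.array([coords[n_idx], coords[o_idx], coords.mean(axis=0)])
    dst = np.array([target_n, target_o, _POCKET_CENTER])
    rot, _ = Rotation.align_vectors(dst - dst.mean(axis=0), src - src.mean(axis=0))
    planted = rot.apply(coords - src.mean(axis=0)) + dst.mean(axis=0)

    # spin about the anchor axis: both hydrogen bonds are preserved (the
    # anchored atoms sit on the axis) while the ring tilts away from the
    # backbone; keep the spin with the best hinge-only score
    from .chem_io import Receptor
    from .energy import binding_free_energy
    from .screen import detect_hinge_hbonds

    ridx: dict[int, list[int]] = {}
    for a in hinge_atoms:
        ridx.setdefault(a.residue[1], []).append(a.serial)
    hinge_rec = Receptor(atoms=list(hinge_atoms), residue_index=ridx,
                         pocket_center=_POCKET_CENTER.copy())
    # the phenol O-H torsion is not a search degree of freedom (terminal OH),
    # so point it at the acceptor during construction: rotate H about the
    # C-O axis to the position closest to the 791 carbonyl oxygen
    rd_h = next(
        nb.GetIdx() for nb in rd.GetAtomWithIdx(o_idx).GetNeighbors()
        if nb.GetSymbol() == "H"
    )
    rd_c = next(
        nb.GetIdx() for nb in rd.GetAtomWithIdx(o_idx).GetNeighbors()
        if nb.GetSymbol() != "H"
    )
    acceptor_o = by_res[791]["O"]

    def _aim_hydroxyl(xyz: np.ndarray) -> np.ndarray:
        out = xyz.copy()
        axis = out[o_idx] - out[rd_c]
        axis = axis / np.linalg.norm(axis)
        best_h, best_d = out[rd_h], np.inf
        for theta in range(0, 360, 5):
            rot = Rotation.from_rotvec(np.radians(theta) * axis)
            h = rot.apply(out[rd_h] - out[o_idx]) + out[o_idx]
            d = np.linalg.norm(h - acceptor_o)
            if d < best_d:
                best_h, best_d = h, d
        out[rd_h] = best_h
        return out

    axis = target_n - target_o
    axis = axis / np.linalg.norm(axis)
    pivot = 0.5 * (target_n + target_o)
    best, best_score = _aim_hydroxyl(planted), np.inf
    for theta in range(0, 360, 10):
        spun = Rotation.from_rotvec(np.radians(theta) * axis).apply(planted - pivot) + pivot
        spun = _aim_hydroxyl(spun)
        cand = mol.with_coords(spun)
        n_hb, _ = detect_hinge_hbonds(hinge_rec, cand, None)
        if n_hb < 2:
            continue
        score = binding_free_energy(hinge_rec, cand).total
        if score < best_score:
            best, best_score = spun, score
    return best


def make_planted_binder(
    receptor: Receptor, spec: FixtureSpec
) -> tuple[LigandMolecule, np.ndarray]:
    """A rigid ligand posed so that two hinge hydrogen bonds are in place.

    Returns the ligand *with the planted coordinates as its conformation*
    together with the expected pose center (its centroid); an identity pose
    at that center reproduces the planted geometry exactly.  The receptor's
    lining shell was built with clearance for exactly this geometry, so the
    planted pose sits in an attractive pocket.
    """
    from .search import PoseGenome, apply_pose, polish_pose

    hinge = [receptor.atoms[i] for r in range(791, 796)
             for i in receptor.residue_index[r]]
    planted = _planted_coords(hinge, spec.seed)
    mol = ligand_from_smiles(_PLANTED_SMILES, name="planted_binder", seed=spec.seed)
    planted_mol = mol.with_coords(planted)

    # settle the anchored construction into the score's own local minimum
    # (deterministic Powell polish on the direct score), so the recorded
    # pose region is a genuine minimum of the energy model rather than the
    # idealized anchor geometry
    pose0 = PoseGenome.identity(planted.mean(axis=0), 0)
    refined, _ = polish_pose(planted_mol, receptor, pose0)
    relaxed = apply_pose(planted_mol, refined)
    planted_mol = planted_mol.with_coords(relaxed)
    return planted_mol, relaxed.mean(axis=0)


def make_decoy(spec: FixtureSpec) -> LigandMolecule:
    """An apolar decoy (no N/O): can never satisfy the hinge filter."""
    return ligand_from_smiles("C1CCCCC1", name="apolar_decoy", seed=spec.seed)


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

# Scaffolds carry one substitution site as atom map 1; substituents have one
# dummy-atom attachment point.  Combinations land mostly in the 300-400 amu
# screening window.
_SCAFFOLDS: tuple[str, ...] = (
    "O=C(Nc1ccc2ccccc2c1)c1ccc2cc[cH:1]cc2c1",  # bis-naphthalene amide
    "O=C(Nc1ccc(OC)cc1)c1ccc2cc[cH:1]cc2c1",
    "c1ccc(Nc2ncnc3cc[cH:1]cc23)cc1OC",  # anilinoquinazoline
    "O=C(c1ccc2OCOc2c1)Nc1ccc2cc[cH:1]cc2c1",
    "O=S(=O)(Nc1ccc2ccccc2c1)c1ccc[cH:1]c1",  # arylsulfonamide
    "O=C(Nc1cccc2ccccc12)c1cc[cH:1]s1",
    "COc1ccc(-c2cc(=O)c3cc[cH:1]cc3o2)cc1OC",  # flavone
    "O=C(Nc1ccc(F)cc1)Nc1ccc2cc[cH:1]cc2c1",  # diarylurea
    "c1ccc(-c2nc3cc[cH:1]cc3[nH]c2=O)cc1OC",  # quinazolinone
    "O=C(NCc1ccccc1)c1ccc2cc[cH:1]cc2n1",  # quinoline amide
    "O=C(Nc1ccc2ccccc2c1)c1ccc(OC)c[cH:1]1",
    "O=S(=O)(N1CCCCC1)c1ccc2cc[cH:1]cc2c1",
    "O=C(N1CCN(C)CC1)c1ccc2cc[cH:1]cc2c1",
    "COc1ccc(Nc2ncnc3cc[cH:1]cc23)cc1",
    "O=C(Nc1ccccc1Cl)c1ccc2cc[cH:1]cc2c1",
    "c1cc2c(cc1)c(=O)c1cc[cH:1]cc1o2",  # xanthone
)

_SUBSTITUENTS: tuple[str, ...] = (
    "*C", "*CC", "*CCC", "*CCCC", "*OC", "*OCC", "*F", "*Cl", "*Br",
    "*C(C)C", "*N(C)C", "*C#N", "*C(=O)OC", "*C(F)(F)F", "*OCCOC",
    "*S(=O)(=O)C", "*CCN(C)C", "*Cc1ccccc1", "*OCc1ccccc1",
    "*N1CCOCC1", "*C(=O)N1CCCC1", "*OCCN(C)C",
)

# planted near-duplicate families: one scaffold, homologous substituents
_CLUSTER_SERIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    (_SCAFFOLDS[0], ("*CC", "*CCC", "*CCCC", "*CCCCC")),
    (_SCAFFOLDS[4], ("*OC", "*OCC", "*OCCC", "*OCCCC")),
    (_SCAFFOLDS[11], ("*CC", "*CCC", "*CCCC", "*C(C)C")),
)

_BELOW_WINDOW: tuple[str, ...] = (
    "c1ccccc1O", "CC(=O)Nc1ccccc1", "c1ccc2[nH]ccc2c1", "CC(=O)Oc1ccccc1C(=O)O",
    "Cc1ccccc1N", "OCC(O)CO", "c1ccncc1", "CCOC(=O)C", "NC(=O)c1ccccc1",
    "COc1ccccc1", "Clc1ccccc1Cl", "CC(C)Cc1ccccc1", "O=C1CCCCC1",
    "NCCc1ccccc1", "CN1CCNCC1", "Oc1ccncc1", "CCCCCCO", "c1ccc2ccccc2c1",
)

_ABOVE_WINDOW: tuple[str, ...] = tuple(
    "C" * n for n in range(29, 37)  # long n-alkanes, MW 408-506
) + tuple(
    f"{'C' * n}OC(=O)c1ccccc1C(=O)O{'C' * n}" for n in (9, 10, 11, 12)  # phthalates
) + (
    "COCCOCCOCCOCCOCCOCCOCCOCCOCCOC",
    "CCCCCCCCCCCCCCCCCCOC(=O)CCCCCCCC",
    "C(OCCCCCCCCC)(=O)c1ccc(C(=O)OCCCCCCCCC)cc1",
)


def _site_index(core: Chem.Mol) -> int:
    for atom in core.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            return atom.GetIdx()
    raise ValueError("scaffold has no atom-map-1 site")


def _product_smiles(scaffold: str, substituent: str) -> str | None:
    core = Chem.MolFromSmiles(scaffold)
    if core is None:
        return None
    try:
        prod = attach_fragment(core, _site_index(core), substituent)
    except ValueError:
        return None
    return Chem.MolToSmiles(prod)


def make_library(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[list[LibraryEntry], pd.DataFrame, dict[str, int]]:
    """Generate the synthetic screening library with its ground-truth table.

    Returns ``(entries, truth, expected_counts)``.  ``truth`` has one row
    per molecule (id, SMILES, MW, rule-of-five violations, MW-window flag,
    planted-cluster label); ``expected_counts`` gives the survivor count of
    each filtration stage (MW window → rule of five → Tanimoto-0.8 leader
    clustering) computed from the generated set itself, in order.  Pure
    function of the spec: a fixed seed reproduces files byte for byte.
    """
    lib = spec.library
    rng = np.random.default_rng(spec.seed)

    planted: list[tuple[str, str]] = []  # (smiles, cluster label)
    n_series = min(lib.n_planted_clusters, len(_CLUSTER_SERIES))
    for c, (scaffold, subs) in enumerate(_CLUSTER_SERIES[:n_series]):
        for s in subs[: lib.cluster_size]:
            smi = _product_smiles(scaffold, s)
            if smi is not None:
                planted.append((smi, f"planted{c}"))

    pool: list[str] = []
    seen = {smi for smi, _ in planted}
    for scaffold in _SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            smi = _product_smiles(scaffold, sub)
            if smi is not None and smi not in seen:
                seen.add(smi)
                pool.append(smi)

    from .chem_io import ro5_profile

    def _mw(smi: str) -> float:
        return ro5_profile(Chem.MolFromSmiles(smi)).mw

    in_window_pool = [s for s in pool if 300.0 <= _mw(s) <= 400.0]
    n_planted_in = len(planted)
    n_fill = lib.n_in_window - n_planted_in
    if n_fill < 0:
        raise ValueError("planted clusters exceed the requested in-window count")
    if n_fill > len(in_window_pool):
        raise ValueError(
            f"scaffold pool too small: need {n_fill} in-window, have {len(in_window_pool)}"
        )
    chosen_in = [in_window_pool[i] for i in
                 sorted(rng.choice(len(in_window_pool), size=n_fill, replace=False))]
    below = [s for s in _BELOW_WINDOW if _mw(s) < 300.0]
    above = [s for s in _ABOVE_WINDOW if _mw(s) > 400.0]
    if lib.n_below > len(below) or lib.n_above > len(above):
        raise ValueError("not enough out-of-window molecules in the curated sets")
    chosen_below = [below[i] for i in
                    sorted(rng.choice(len(below), size=lib.n_below, replace=False))]
    chosen_above = [above[i] for i in
                    sorted(rng.choice(len(above), size=lib.n_above, replace=False))]

    records = (
        [(s, lbl) for s, lbl in planted]
        + [(s, "") for s in chosen_in]
        + [(s, "") for s in chosen_below]
        + [(s, "") for s in chosen_above]
    )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    entries: list[LibraryEntry] = []
    rows = []
    for k, (smi, label) in enumerate(records):
        entry = make_library_entry(f"lib{k:04d}", smi)
        entries.append(entry)
        rows.append(
            {
                "id": entry.id,
                "smiles": smi,
                "mw": entry.mw,
                "ro5_violations": entry.ro5_violations,
                "in_mw_window": 300.0 <= entry.mw <= 400.0,
                "planted_cluster": label,
            }
        )
    truth = pd.DataFrame(rows)

    stage_mw = mw_window_filter(entries)
    stage_ro5 = ro5_filter(stage_mw)
    stage_cluster = cluster_by_tanimoto(stage_ro5)
    expected_counts = {
        "library": len(entries),
        "mw_window": len(stage_mw),
        "ro5": len(stage_ro5),
        "cluster": len(stage_cluster),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        smi_lines = [f"{e.smiles}\t{e.id}" for e in entries]
        (out_dir / "library.smi").write_text("\n".join(smi_lines) + "\n")
        truth.to_csv(out_dir / "library_truth.tsv", sep="\t", index=False,
                     float_format="%.4f")
    return entries, truth, expected_counts
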