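"""Two-track selectivity virtual screening.

The pipeline keeps candidates predicted to bind *tightly* to the mutant
kinase and *weakly* to the wild type:

1. library filtration — molecular-weight window (300-400 amu inclusive),
   rule-of-five compliance (at most one violation), and greedy leader
   clustering at Tanimoto 0.8 to strip structural redundancy;
2. docking each survivor against both receptors and rescoring the best pose
   with the full binding free energy function;
3. the energy filter: ΔG(mut) < −10 kcal/mol AND ΔG(wt) > −6 kcal/mol
   (strict inequalities on both tracks), which forces a selectivity gap
   ΔG(wt) − ΔG(mut) > 4 kcal/mol for every survivor;
4. the hinge filter: at least two hydrogen bonds to backbone groups of the
   hinge residues (791-795 by default) at heavy-atom distance < 3.5 Å.

Records for every molecule — passing or not — are retained with their
scores, hinge counts and per-flag outcomes, so the funnel is fully
auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import LigandMolecule, Receptor, ro5_profile
from .grids import GridMapSet, build_grid_maps, pocket_box
from .params import EnergyParameters, ParameterTables, default_parameters, default_tables
from .search import PoseGenome, SearchConfig, apply_pose, optimize_pose, rescore_direct

log = logging.getLogger(__name__)

__all__ = [
    "LibraryEntry",
    "ScreenThresholds",
    "ScreenRecord",
    "make_library_entry",
    "mw_window_filter",
    "ro5_filter",
    "cluster_by_tanimoto",
    "tanimoto",
    "detect_hinge_hbonds",
    "two_track_screen",
    "write_records_tsv",
]

FINGERPRINT_BITS = 2048


@dataclass
class LibraryEntry:
    """One library molecule with the properties the filtration stages need."""

    id: str
    smiles: str
    mw: float
    fingerprint: object  # RDKit ExplicitBitVect, fixed length per library
    ro5_violations: int
    mol: LigandMolecule | None = None


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs of the energy and hinge filters (strict inequalities)."""

    dg_mut_max: float = -10.0  # kcal/mol; pass requires dg_mut < this
    dg_wt_min: float = -6.0  # kcal/mol; pass requires dg_wt > this
    hbond_distance_max: float = 3.5  # Å, heavy-atom donor-acceptor distance
    min_hinge_hbonds: int = 2
    hinge_residues: frozenset[int] = frozenset(range(791, 796))

    def __post_init__(self) -> None:
        if not self.dg_mut_max < self.dg_wt_min:
            raise ValueError("dg_mut_max must be below dg_wt_min")
        if self.hbond_distance_max <= 0:
            raise ValueError("hbond_distance_max must be positive")


@dataclass
class ScreenRecord:
    """Per-molecule two-track outcome."""

    molecule_id: str
    dg_mut: float
    dg_wt: float
    hinge_hbond_count: int
    pass_energy: bool
    pass_hinge: bool
    seed: int = 0
    error: str = ""

    @property
    def pass_all(self) -> bool:
        return self.pass_energy and self.pass_hinge

    @classmethod
    def evaluate(
        cls,
        molecule_id: str,
        dg_mut: float,
        dg_wt: float,
        hinge_hbond_count: int,
        thresholds: ScreenThresholds,
        seed: int = 0,
    ) -> "ScreenRecord":
        return cls(
            molecule_id=molecule_id,
            dg_mut=dg_mut,
            dg_wt=dg_wt,
            hinge_hbond_count=hinge_hbond_count,
            pass_energy=(dg_mut < thresholds.dg_mut_max) and (dg_wt > thresholds.dg_wt_min),
            pass_hinge=hinge_hbond_count >= thresholds.min_hinge_hbonds,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# library filtration
# ---------------------------------------------------------------------------

_FP_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=FINGERPRINT_BITS)


def make_library_entry(
    entry_id: str, smiles: str, mol: LigandMolecule | None = None
) -> LibraryEntry:
    """Compute MW, fingerprint and rule-of-five count for one library molecule."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparsable SMILES for {entry_id}: {smiles!r}")
    prof = ro5_profile(rdmol)
    return LibraryEntry(
        id=entry_id,
        smiles=smiles,
        mw=prof.mw,
        fingerprint=_FP_GEN.GetFingerprint(rdmol),
        ro5_violations=prof.violations,
        mol=mol,
    )


def mw_window_filter(
    entries: list[LibraryEntry], low: float = 300.0, high: float = 400.0
) -> list[LibraryEntry]:
    """Keep molecules with low <= MW <= high amu (inclusive bounds)."""
    return [e for e in entries if low <= e.mw <= high]


def ro5_filter(entries: list[LibraryEntry], max_violations: int = 1) -> list[LibraryEntry]:
    """Keep rule-of-five-compliant molecules (at most ``max_violations``)."""
    return [e for e in entries if e.ro5_violations <= max_violations]


def tanimoto(fp_a, fp_b) -> float:
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def cluster_by_tanimoto(
    entries: list[LibraryEntry], cutoff: float = 0.8
) -> list[LibraryEntry]:
    """Greedy leader clustering in input order; returns the representatives.

    An entry joins the first existing representative whose Tanimoto
    similarity exceeds ``cutoff``, otherwise it founds a new cluster.
    Deterministic for a fixed input order.
    """
    reps: list[LibraryEntry] = []
    for e in entries:
        if not any(tanimoto(e.fingerprint, r.fingerprint) > cutoff for r in reps):
            reps.append(e)
    return reps


# ---------------------------------------------------------------------------
# hinge hydrogen-bond filter
# ---------------------------------------------------------------------------

def detect_hinge_hbonds(
    receptor: Receptor,
    mol: LigandMolecule,
    pose: PoseGenome | None,
    thresholds: ScreenThresholds | None = None,
) -> tuple[int, list[tuple[int, int, float]]]:
    """Count hydrogen bonds between the ligand and hinge backbone groups.

    A contact counts when the heavy-atom distance is strictly below the
    threshold and the donor/acceptor roles are complementary: a ligand N/O
    *without* attached hydrogen may accept from a hinge backbone amide
    nitrogen, and a ligand N/O *with* attached hydrogen may donate to a
    hinge backbone carbonyl oxygen.  Only the distance criterion is applied,
    no angle term.  Returns (count, [(ligand atom, receptor atom, distance)]).
    """
    thresholds = thresholds or ScreenThresholds()
    hinge = set(thresholds.hinge_residues)
    missing = sorted(r for r in hinge if r not in receptor.residue_index)
    if missing:
        raise ValueError(f"hinge residues missing from receptor: {missing}")

    coords = apply_pose(mol, pose) if pose is not None else mol.coords

    backbone_n: list[int] = []
    backbone_o: list[int] = []
    for r in sorted(hinge):
        for ai in receptor.residue_index[r]:
            a = receptor.atoms[ai]
            if not a.is_backbone:
                continue
            if a.name == "N":
                backbone_n.append(ai)
            elif a.name == "O":
                backbone_o.append(ai)

    has_h = {b.i for b in mol.bonds if mol.atoms[b.j].element == "H"} | {
        b.j for b in mol.bonds if mol.atoms[b.i].element == "H"
    }
    contacts: list[tuple[int, int, float]] = []
    for li, atom in enumerate(mol.atoms):
        if atom.element not in ("N", "O"):
            continue
        partners = backbone_o if li in has_h else backbone_n
        for ri in partners:
            d = float(np.linalg.norm(coords[li] - receptor.atoms[ri].coords))
            if d < thresholds.hbond_distance_max:
                contacts.append((li, ri, d))
    return len(contacts), contacts


# ---------------------------------------------------------------------------
# the two-track screen
# ---------------------------------------------------------------------------

def two_track_screen(
    library: list[LigandMolecule],
    receptor_mut: Receptor,
    receptor_wt: Receptor,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    thresholds: ScreenThresholds | None = None,
    search_config: SearchConfig | None = None,
    maps_mut: GridMapSet | None = None,
    maps_wt: GridMapSet | None = None,
    grid_spacing: float = 0.5,
    box_half_width: float = 8.0,
) -> list[ScreenRecord]:
    """Dock and rescore every molecule against both receptors.

    Each molecule gets its own seed drawn from an explicit stream spawned
    off the search seed, recorded in its :class:`ScreenRecord`, so any
    single molecule's docking is reproducible in isolation.  Per-molecule
    failures are logged and recorded as non-passing; they never abort the
    batch.  Output order follows the input library order.
    """
    params = params or default_parameters()
    tables = tables or default_tables()
    thresholds = thresholds or ScreenThresholds()
    search_config = search_config or SearchConfig()

    def _maps(receptor: Receptor, given: GridMapSet | None) -> GridMapSet:
        if given is not None:
            return given
        center = (
            receptor.pocket_center
            if receptor.pocket_center is not None
            else receptor.coords.mean(axis=0)
        )
        box = pocket_box(center, half_width=box_half_width, spacing=grid_spacing)
        return build_grid_maps(receptor, box, params, tables)

    if not library:
        return []
    maps_mut = _maps(receptor_mut, maps_mut)
    maps_wt = _maps(receptor_wt, maps_wt)

    seeds = np.random.SeedSequence(search_config.seed).generate_state(len(library))
    records: list[ScreenRecord] = []
    for mol, seed in zip(library, seeds):
        seed = int(seed % (2**31))
        cfg = SearchConfig(
            seed=seed,
            n_starts=search_config.n_starts,
            n_steps=search_config.n_steps,
            translation_scale=search_config.translation_scale,
            rotation_scale=search_config.rotation_scale,
            torsion_scale=search_config.torsion_scale,
            t_start=search_config.t_start,
            t_end=search_config.t_end,
            greedy_rounds=search_config.greedy_rounds,
            start_spread=search_config.start_spread,
        )
        try:
            pose_mut, _ = optimize_pose(mol, maps_mut, cfg, params, tables)
            pose_wt, _ = optimize_pose(mol, maps_wt, cfg, params, tables)
            dg_mut = rescore_direct(receptor_mut, mol, pose_mut, params, tables).total
            dg_wt = rescore_direct(receptor_wt, mol, pose_wt, params, tables).total
            n_hinge, _ = detect_hinge_hbonds(receptor_mut, mol, pose_mut, thresholds)
            records.append(
                ScreenRecord.evaluate(mol.name, dg_mut, dg_wt, n_hinge, thresholds, seed)
            )
        except Exception as exc:  # noqa: BLE001 — per-molecule isolation
            log.warning("molecule %s failed: %s", mol.name, exc)
            records.append(
                ScreenRecord(
                    molecule_id=mol.name, dg_mut=float("nan"), dg_wt=float("nan"),
                    hinge_hbond_count=0, pass_energy=False, pass_hinge=False,
                    seed=seed, error=str(exc),
                )
            )
    return records


def write_records_tsv(records: list[ScreenRecord], path: str | Path) -> None:
    """Stable plain-text record table (one row per molecule, fixed formatting)."""
    lines = ["molecule_id\tdg_mut\tdg_wt\thinge_hbonds\tpass_energy\tpass_hinge\tpass\tseed\terror"]
    for r in records:
        lines.append(
            f"{r.molecule_id}\t{r.dg_mut:.6f}\t{r.dg_wt:.6f}\t{r.hinge_hbond_count}"
            f"\t{int(r.pass_energy)}\t{int(r.pass_hinge)}\t{int(r.pass_all)}"
            f"\t{r.seed}\t{r.error}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_run_manifest(
    path: str | Path,
    seed: int,
    tables: ParameterTables,
    thresholds: ScreenThresholds,
    extra: dict | None = None,
) -> None:
    manifest = {
        "seed": seed,
        "parameter_hash": tables.provenance_hash(),
        "fingerprint": {"kind": "rdkit-path", "bits": FINGERPRINT_BITS},
        "thresholds": {
            "dg_mut_max": thresholds.dg_mut_max,
            "dg_wt_min": thresholds.dg_wt_min,
            "hbond_distance_max": thresholds.hbond_distance_max,
            "min_hinge_hbonds": thresholds.min_hinge_hbonds,
            "hinge_residues": sorted(thresholds.hinge_residues),
        },
    }
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
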