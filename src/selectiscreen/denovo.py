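"""Structure-based de novo design by bounded substituent enumeration.

Starting from a screening hit, derivatives are generated by attaching
fragments from a library at up to two marked substitution sites (replacing
one hydrogen per site).  The enumeration is exhaustive and deterministic —
every combination of (fragment or H) at each site, the unmodified parent
excluded, de-duplicated by canonical SMILES — which makes the combinatorics
exactly predictable: with f fragments and two sites, (f+1)² − 1 derivatives
exist before de-duplication.

Selection then mirrors the screening pipeline in two steps:

1. a *gas-phase* prefilter: the derivative must out-score the parent hit
   against the mutant using the first four energy terms only (van der
   Waals, hydrogen bond, electrostatic, torsional — no dehydration), and
   must satisfy the bioavailability (rule-of-five) profile;
2. a full two-track rescore with the complete function including the
   dehydration term: survivors must bind the mutant more tightly than the
   wild type with a selectivity gap strictly larger than 5 kcal/mol, and
   are ranked by mutant affinity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_io import LigandMolecule, Receptor, ligand_from_rdkit, ro5_profile
from .grids import GridMapSet
from .params import EnergyParameters, ParameterTables, default_parameters, default_tables
from .search import SearchConfig, optimize_pose, rescore_direct

log = logging.getLogger(__name__)

__all__ = [
    "SubstitutionSite",
    "DenovoConfig",
    "DenovoCandidate",
    "attach_fragment",
    "enumerate_derivatives",
    "empirical_prefilter",
    "two_track_select",
    "sites_from_atom_maps",
]


@dataclass(frozen=True)
class SubstitutionSite:
    """An attachment point on the core: a heavy atom with a replaceable H."""

    atom_index: int
    label: str = "R"


@dataclass(frozen=True)
class DenovoConfig:
    max_sites: int = 2
    selectivity_gap_min: float = 5.0  # kcal/mol, strict
    max_ro5_violations: int = 1
    embed_seed: int = 2023

    def __post_init__(self) -> None:
        if self.max_sites < 1:
            raise ValueError("max_sites must be >= 1")
        if self.selectivity_gap_min < 0:
            raise ValueError("selectivity gap must be non-negative")


@dataclass
class DenovoCandidate:
    mol: LigandMolecule
    substitutions: dict[str, str]  # site label -> fragment SMILES ("" = H)
    dg_gas_mut: float | None = None
    dg_mut: float | None = None
    dg_wt: float | None = None

    @property
    def gap(self) -> float | None:
        if self.dg_mut is None or self.dg_wt is None:
            return None
        return self.dg_wt - self.dg_mut


def sites_from_atom_maps(core: Chem.Mol) -> list[SubstitutionSite]:
    """Read substitution sites from atom-map numbers on the core (R1 = map 1)."""
    sites = []
    for atom in core.GetAtoms():
        n = atom.GetAtomMapNum()
        if n > 0:
            sites.append(SubstitutionSite(atom.GetIdx(), f"R{n}"))
    return sorted(sites, key=lambda s: s.label)


def attach_fragment(core: Chem.Mol, site_index: int, fragment_smiles: str) -> Chem.Mol:
    """Replace one hydrogen on ``core`` atom ``site_index`` with a fragment.

    The fragment is given as SMILES with exactly one dummy-atom attachment
    point, e.g. ``"*OC"`` for a methoxy group.  Returns a sanitized new
    molecule; raises ValueError when the attachment is impossible.
    """
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        raise ValueError(f"unparsable fragment SMILES: {fragment_smiles!r}")
    dummies = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(f"fragment {fragment_smiles!r} must have exactly one attachment point")
    site_atom = core.GetAtomWithIdx(site_index)
    if site_atom.GetTotalNumHs() < 1:
        raise ValueError(f"core atom {site_index} has no hydrogen to replace")

    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    offset = core.GetNumAtoms()
    dummy = offset + dummies[0]
    neighbor = combined.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    combined.AddBond(site_index, neighbor, Chem.BondType.SINGLE)
    combined.RemoveAtom(dummy)
    site = combined.GetAtomWithIdx(site_index)
    if site.GetNumExplicitHs() > 0:
        site.SetNumExplicitHs(site.GetNumExplicitHs() - 1)
    else:
        site.SetNoImplicit(False)
    out = combined.GetMol()
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    Chem.SanitizeMol(out)
    return out


def enumerate_derivatives(
    core: Chem.Mol | LigandMolecule,
    sites: list[SubstitutionSite],
    fragments: list[str],
    config: DenovoConfig | None = None,
) -> list[DenovoCandidate]:
    """All combinations of (fragment or H) over the sites, parent excluded.

    Derivatives are prepared (explicit H, seeded 3D embedding, charges,
    types) and de-duplicated by canonical SMILES; attachment failures are
    logged and skipped.  Enumeration order is deterministic: fragments in
    input order, sites in label order, the all-H parent dropped.
    """
    config = config or DenovoConfig()
    if isinstance(core, LigandMolecule):
        core = Chem.RemoveHs(core.rdkit_mol)
    if len(sites) > config.max_sites:
        raise ValueError(f"at most {config.max_sites} substitution sites allowed")

    choices = [""] + list(fragments)  # "" keeps the hydrogen
    out: list[DenovoCandidate] = []
    seen: set[str] = set()
    counter = 0
    for combo in itertools.product(choices, repeat=len(sites)):
        if all(c == "" for c in combo):
            continue  # unmodified parent
        counter += 1
        mol = Chem.Mol(core)
        try:
            # attach in descending atom index so earlier indices stay valid
            order = sorted(
                [(s, c) for s, c in zip(sites, combo) if c],
                key=lambda sc: -sc[0].atom_index,
            )
            for site, frag in order:
                mol = attach_fragment(mol, site.atom_index, frag)
            smiles = Chem.MolToSmiles(mol)
            if smiles in seen:
                continue
            seen.add(smiles)
            name = "deriv_" + "_".join(c if c else "H" for c in combo)
            prepared = ligand_from_rdkit(
                Chem.MolFromSmiles(smiles), name=name,
                seed=config.embed_seed + counter,
            )
            out.append(
                DenovoCandidate(
                    mol=prepared,
                    substitutions={s.label: c for s, c in zip(sites, combo)},
                )
            )
        except (ValueError, Chem.rdchem.KekulizeException) as exc:
            log.warning("skipping derivative %s: %s", combo, exc)
    return out


def _dock_and_rescore(
    mol: LigandMolecule,
    receptor: Receptor,
    maps: GridMapSet,
    params: EnergyParameters,
    tables: ParameterTables,
    search_config: SearchConfig,
):
    pose, _ = optimize_pose(mol, maps, search_config, params, tables)
    return rescore_direct(receptor, mol, pose, params, tables)


def empirical_prefilter(
    derivatives: list[DenovoCandidate],
    receptor_mut: Receptor,
    maps_mut: GridMapSet,
    parent: LigandMolecule,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    search_config: SearchConfig | None = None,
    config: DenovoConfig | None = None,
) -> list[DenovoCandidate]:
    """Keep derivatives strictly out-scoring the parent, gas phase, on the mutant.

    The score is the four-term empirical function (no dehydration).  The
    rule-of-five bioavailability profile must also pass.  Order-preserving
    and idempotent: surviving candidates keep their ``dg_gas_mut``.
    """
    params = params or default_parameters()
    tables = tables or default_tables()
    search_config = search_config or SearchConfig()
    config = config or DenovoConfig()

    parent_gas = _dock_and_rescore(
        parent, receptor_mut, maps_mut, params, tables, search_config
    ).gas_phase
    out: list[DenovoCandidate] = []
    for cand in derivatives:
        if cand.dg_gas_mut is None:
            cand.dg_gas_mut = _dock_and_rescore(
                cand.mol, receptor_mut, maps_mut, params, tables, search_config
            ).gas_phase
        if cand.dg_gas_mut >= parent_gas:
            continue
        if ro5_profile(cand.mol).violations > config.max_ro5_violations:
            continue
        out.append(cand)
    return out


def two_track_select(
    candidates: list[DenovoCandidate],
    receptor_mut: Receptor,
    receptor_wt: Receptor,
    maps_mut: GridMapSet,
    maps_wt: GridMapSet,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    search_config: SearchConfig | None = None,
    config: DenovoConfig | None = None,
) -> list[DenovoCandidate]:
    """Full two-track rescore; keep selective candidates, ranked by ΔG(mut).

    A candidate survives when it binds the mutant more tightly than the
    wild type AND the gap ΔG(wt) − ΔG(mut) is strictly larger than the
    configured minimum (5 kcal/mol by default; a gap of exactly 5.0 is
    excluded).
    """
    params = params or default_parameters()
    tables = tables or default_tables()
    search_config = search_config or SearchConfig()
    config = config or DenovoConfig()

    kept: list[DenovoCandidate] = []
    for cand in candidates:
        if cand.dg_mut is None:
            cand.dg_mut = _dock_and_rescore(
                cand.mol, receptor_mut, maps_mut, params, tables, search_config
            ).total
        if cand.dg_wt is None:
            cand.dg_wt = _dock_and_rescore(
                cand.mol, receptor_wt, maps_wt, params, tables, search_config
            ).total
        if cand.dg_mut < cand.dg_wt and (cand.dg_wt - cand.dg_mut) > config.selectivity_gap_min:
            kept.append(cand)
    kept.sort(key=lambda c: c.dg_mut)
    return kept
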