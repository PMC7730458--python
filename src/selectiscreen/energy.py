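"""The modified empirical binding free energy function ΔG_b^aq.

The score of a receptor-ligand pose is the weighted sum of five terms::

    ΔG_b^aq = W_vdW   Σ_ij (A_ij/r_ij^12 − B_ij/r_ij^6)                 van der Waals
            + W_hbond Σ_ij E(t) (C_ij/r_ij^12 − D_ij/r_ij^10)           hydrogen bonds
            + W_elec  Σ_ij q_i q_j / (ε(r_ij) r_ij)                     electrostatics
            + W_tor   N_tor                                             torsional entropy
            + Σ_i S_i max(0, O_i^max − Σ_{j≠i} V_j e^{−r_ij²/2σ²})      ligand dehydration

The first four terms run over receptor-ligand atom pairs (a pair uses the
12-10 well instead of the 12-6 well when it is a polar-hydrogen/acceptor
pair) and make up the gas-phase binding free energy.  The last term is the
negative of the ligand hydration free energy under a solvent-contact model:
each ligand atom i owns a maximum water-accessible occupancy O_i^max that is
depleted by the Gaussian-weighted volumes of the other *ligand* atoms, so
the term is a pure property of the ligand conformation and is bit-identical
under any change of receptor coordinates.

E(t) is the hydrogen-bond directionality weight: cos² of the deviation t of
the D-H···A geometry from linearity, zero beyond 90°.  ε(r) is the
distance-dependent sigmoidal dielectric screening function.

All routines exist in two flavours: scalar/closed-form primitives (exported
for tests and grid builders) and the vectorized :func:`binding_free_energy`
that produces a :class:`ScoreBreakdown`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem_io import LigandMolecule, Receptor
from .params import EnergyParameters, ParameterTables

__all__ = [
    "ScoreBreakdown",
    "HBondGeometry",
    "lj_12_6",
    "hb_12_10",
    "directionality_weight",
    "sigmoidal_dielectric",
    "coulomb_energy",
    "torsion_penalty",
    "ligand_occupancy",
    "dehydration_term",
    "binding_free_energy",
]


@dataclass(frozen=True)
class ScoreBreakdown:
    """The five term values (kcal/mol) and their total ΔG_b^aq."""

    e_vdw: float
    e_hbond: float
    e_elec: float
    e_tor: float
    e_dehydration: float

    @property
    def total(self) -> float:
        return self.e_vdw + self.e_hbond + self.e_elec + self.e_tor + self.e_dehydration

    @property
    def gas_phase(self) -> float:
        """First four terms only (no dehydration) — the prefilter score."""
        return self.e_vdw + self.e_hbond + self.e_elec + self.e_tor

    def as_dict(self) -> dict[str, float]:
        return {
            "e_vdw": self.e_vdw,
            "e_hbond": self.e_hbond,
            "e_elec": self.e_elec,
            "e_tor": self.e_tor,
            "e_dehydration": self.e_dehydration,
            "total": self.total,
        }


@dataclass(frozen=True)
class HBondGeometry:
    """Donor-H···acceptor geometry; t is the deviation (deg) from linearity."""

    donor: np.ndarray
    hydrogen: np.ndarray
    acceptor: np.ndarray

    @property
    def deviation_angle(self) -> float:
        u = np.asarray(self.acceptor, float) - np.asarray(self.hydrogen, float)
        v = np.asarray(self.hydrogen, float) - np.asarray(self.donor, float)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
        return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# scalar primitives
# ---------------------------------------------------------------------------

def lj_12_6(r: float, a: float, b: float, inner_clamp: float = 0.5) -> float:
    """12-6 Lennard-Jones energy A/r^12 − B/r^6 (kcal/mol).

    Distances below ``inner_clamp`` are clamped to it, capping the repulsive
    wall at a large finite value so clashed poses stay comparable.
    """
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    r = max(r, inner_clamp)
    inv6 = 1.0 / r**6
    return a * inv6 * inv6 - b * inv6


def directionality_weight(t: float, cutoff: float = 90.0) -> float:
    """Hydrogen-bond directionality E(t) = cos² t for t ≤ cutoff, else 0."""
    if t >= cutoff:
        return 0.0
    return math.cos(math.radians(t)) ** 2


def hb_12_10(
    r: float, c: float, d: float, t: float = 0.0,
    cutoff: float = 90.0, inner_clamp: float = 0.5,
) -> float:
    """Directional 12-10 hydrogen-bond energy E(t)·(C/r^12 − D/r^10)."""
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    r = max(r, inner_clamp)
    w = directionality_weight(t, cutoff)
    if w == 0.0:
        return 0.0
    inv2 = 1.0 / (r * r)
    inv10 = inv2**5
    return w * (c * inv10 * inv2 - d * inv10)


def sigmoidal_dielectric(r, constants=(-8.5525, 86.9525, 7.7839, 0.003627)):
    """Distance-dependent sigmoidal dielectric ε(r) = A + B/(1 + k e^{−λBr}).

    Monotone non-decreasing from ε(0) ≈ 1.35 to the bulk value A + B = 78.4,
    modelling the long-range screening of charges by solvent.  Accepts a
    scalar or an array of distances.
    """
    a, b, k, lam = constants
    r = np.asarray(r, dtype=float)
    eps = a + b / (1.0 + k * np.exp(-lam * b * r))
    return float(eps) if eps.ndim == 0 else eps


def coulomb_energy(
    q_i: float, q_j: float, r: float, params: EnergyParameters | None = None
) -> float:
    """Screened Coulomb energy 332·q_i q_j / (ε(r)·r) in kcal/mol."""
    params = params or EnergyParameters()
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    r_eff = max(r, params.inner_clamp)
    eps = sigmoidal_dielectric(r_eff, params.dielectric_constants)
    return params.coulomb_constant * q_i * q_j / (eps * r_eff)


def torsion_penalty(n_tor: int, w_tor: float) -> float:
    """Entropic penalty W_tor · N_tor for freezing rotatable bonds on binding."""
    if n_tor < 0:
        raise ValueError("n_tor must be non-negative")
    return w_tor * n_tor


# ---------------------------------------------------------------------------
# dehydration (solvent-contact) term
# ---------------------------------------------------------------------------

def ligand_occupancy(
    i: int, mol: LigandMolecule, sigma: float, tables: ParameterTables | None = None
) -> float:
    """Gaussian-weighted occupancy Σ_{j≠i} V_j e^{−r_ij²/2σ²} of atom i (Å³)."""
    from .params import default_tables

    tables = tables or default_tables()
    coords = mol.coords
    _, v, _ = tables.hydration.arrays(mol.atom_types)
    d2 = np.sum((coords - coords[i]) ** 2, axis=1)
    w = v * np.exp(-d2 / (2.0 * sigma * sigma))
    return float(np.sum(w) - w[i])


def dehydration_term(
    mol: LigandMolecule,
    tables: ParameterTables | None = None,
    sigma: float = 3.5,
) -> float:
    """Ligand dehydration penalty Σ_i S_i max(0, O_i^max − occupancy_i).

    Evaluated on the free-ligand conformation only: receptor atoms never
    enter the occupancy sum, so the term is invariant to receptor
    coordinates.  Occupancy in excess of O^max is clamped so that a buried
    atom contributes zero rather than a negative exposure.
    """
    from .params import default_tables

    tables = tables or default_tables()
    coords = mol.coords
    s, v, o_max = tables.hydration.arrays(mol.atom_types)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    g = np.exp(-d2 / (2.0 * sigma * sigma)) * v[None, :]
    np.fill_diagonal(g, 0.0)
    exposure = np.clip(o_max - g.sum(axis=1), 0.0, None)
    return float(np.dot(s, exposure))


# ---------------------------------------------------------------------------
# full pose score
# ---------------------------------------------------------------------------

def _pairwise_terms(
    rec_coords: np.ndarray,
    rec_types: list[str],
    rec_charges: np.ndarray,
    lig_coords: np.ndarray,
    lig_types: list[str],
    lig_charges: np.ndarray,
    et: np.ndarray | None,
    params: EnergyParameters,
    tables: ParameterTables,
) -> tuple[float, float, float]:
    """Raw (unweighted) vdW, H-bond and electrostatic pair sums."""
    d = np.linalg.norm(rec_coords[:, None, :] - lig_coords[None, :, :], axis=2)
    within = d <= params.nonbonded_cutoff
    d_eff = np.maximum(d, params.inner_clamp)

    a, b, hb_mask = tables.pair.matrices(rec_types, lig_types)
    inv2 = 1.0 / (d_eff * d_eff)
    inv6 = inv2**3
    inv10 = inv2**5
    inv12 = inv6 * inv6

    lj = a * inv12 - b * inv6
    e_vdw = float(np.sum(lj[within & ~hb_mask]))

    hb = a * inv12 - b * inv10
    if et is not None:
        hb = hb * et
    e_hbond = float(np.sum(hb[within & hb_mask]))

    eps = sigmoidal_dielectric(d_eff, params.dielectric_constants)
    coul = params.coulomb_constant * np.outer(rec_charges, lig_charges) / (eps * d_eff)
    e_elec = float(np.sum(coul[within]))
    return e_vdw, e_hbond, e_elec


def _directionality_matrix(
    receptor: Receptor,
    mol: LigandMolecule,
    lig_coords: np.ndarray,
    params: EnergyParameters,
) -> np.ndarray:
    """E(t) factors for every (receptor atom, ligand atom) pair.

    Only polar-hydrogen/heavy-atom pairs get a geometric factor; the
    deviation angle t is measured at the hydrogen of the pair, with the
    donor heavy atom found through the covalent topology (ligand) or by
    proximity (receptor).  Non-hydrogen-bonding pairs keep a factor of 1 —
    they are masked out by the pair table anyway.
    """
    n_rec, n_lig = len(receptor.atoms), len(mol.atoms)
    et = np.ones((n_rec, n_lig))
    rec_coords = receptor.coords
    rec_donor = receptor.donor_heavy_of_hydrogen()
    lig_donor = mol.donor_heavy_of_hydrogen()
    cutoff = params.hbond_angle_cutoff
    cut2 = params.nonbonded_cutoff**2

    for ih, idonor in rec_donor.items():
        h, dnr = rec_coords[ih], rec_coords[idonor]
        for j in range(n_lig):
            if np.sum((lig_coords[j] - h) ** 2) > cut2:
                continue
            t = HBondGeometry(dnr, h, lig_coords[j]).deviation_angle
            et[ih, j] = directionality_weight(t, cutoff)
    for jh, jdonor in lig_donor.items():
        h, dnr = lig_coords[jh], lig_coords[jdonor]
        for i in range(n_rec):
            if np.sum((rec_coords[i] - h) ** 2) > cut2:
                continue
            t = HBondGeometry(dnr, h, rec_coords[i]).deviation_angle
            et[i, jh] = directionality_weight(t, cutoff)
    return et


def binding_free_energy(
    receptor: Receptor,
    mol: LigandMolecule,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    lig_coords: np.ndarray | None = None,
    directional: bool = True,
) -> ScoreBreakdown:
    """Evaluate ΔG_b^aq for a ligand posed in the receptor frame.

    ``lig_coords`` overrides the ligand's stored coordinates (the pose);
    ``directional=False`` scores hydrogen bonds at the E(t)=1 upper bound,
    which is the treatment used while building grid maps.
    """
    from .params import default_parameters, default_tables

    params = params or default_parameters()
    tables = tables or default_tables()
    if lig_coords is None:
        lig_coords = mol.coords
    lig_coords = np.asarray(lig_coords, dtype=float)

    bad = [a.serial for a in mol.atoms if not a.atom_type] + [
        a.serial for a in receptor.atoms if not a.atom_type
    ]
    if bad:
        raise ValueError(f"untyped atoms: {bad}")

    et = (
        _directionality_matrix(receptor, mol, lig_coords, params)
        if directional
        else None
    )
    raw_vdw, raw_hb, raw_elec = _pairwise_terms(
        receptor.coords, receptor.atom_types, receptor.charges,
        lig_coords, mol.atom_types, mol.charges,
        et, params, tables,
    )
    posed = mol.with_coords(lig_coords)
    return ScoreBreakdown(
        e_vdw=params.w_vdw * raw_vdw,
        e_hbond=params.w_hbond * raw_hb,
        e_elec=params.w_elec * raw_elec,
        e_tor=torsion_penalty(mol.n_tor, params.w_tor),
        e_dehydration=dehydration_term(posed, tables, params.sigma),
    )
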