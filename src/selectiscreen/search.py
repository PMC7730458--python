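"""Seeded stochastic pose optimization over grid maps.

A pose is a rigid-body placement (translation of the ligand centroid plus a
unit-quaternion orientation) together with one angle per rotatable bond.
The optimizer is multi-start Metropolis annealing on the grid score with a
greedy terminal descent over a shrinking move ladder — a deliberately
simple, fully seeded engine: the scientific content of this package is the
scoring function, not the optimizer, so a transparent annealer that returns
bit-identical results for identical (inputs, seed) is preferred over a
genetic algorithm.

Final poses are rescored with :func:`rescore_direct`, the exact pair-sum
evaluation including the angular hydrogen-bond factor E(t); that value is
the ΔG used by every downstream filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import ChemIOError, LigandMolecule, Receptor
from .energy import ScoreBreakdown, binding_free_energy
from .grids import GridMapSet, grid_score
from .params import EnergyParameters, ParameterTables, default_parameters, default_tables

__all__ = [
    "PoseGenome",
    "SearchConfig",
    "apply_pose",
    "optimize_pose",
    "rescore_direct",
    "rotatable_bond_axes",
]


@dataclass
class PoseGenome:
    """Rigid-body + torsional degrees of freedom of one pose."""

    translation: np.ndarray  # Å, centroid position of the posed ligand
    orientation: np.ndarray  # unit quaternion (x, y, z, w)
    torsions: np.ndarray = field(default_factory=lambda: np.zeros(0))  # degrees

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(q)
        if norm == 0:
            raise ValueError("orientation quaternion must be nonzero")
        self.orientation = q / norm
        self.torsions = (np.asarray(self.torsions, dtype=float) + 180.0) % 360.0 - 180.0

    @classmethod
    def identity(cls, translation, n_tor: int = 0) -> "PoseGenome":
        return cls(np.asarray(translation, float), np.array([0.0, 0.0, 0.0, 1.0]),
                   np.zeros(n_tor))

    def copy(self) -> "PoseGenome":
        return PoseGenome(self.translation.copy(), self.orientation.copy(),
                          self.torsions.copy())


@dataclass(frozen=True)
class SearchConfig:
    """Search budget and move scales; everything is derived from ``seed``."""

    seed: int = 7
    n_starts: int = 8
    n_steps: int = 150
    translation_scale: float = 1.0  # Å
    rotation_scale: float = 20.0  # degrees
    torsion_scale: float = 30.0  # degrees
    t_start: float = 2.0  # kcal/mol, initial Metropolis temperature
    t_end: float = 0.1
    greedy_rounds: int = 40  # improvement tries per rung of the descent ladder
    start_spread: float = 2.0  # Å, spread of random starts around the seed point

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.n_steps < 0:
            raise ValueError("n_starts must be >= 1 and n_steps >= 0")


def rotatable_bond_axes(mol: LigandMolecule) -> list[tuple[int, int, np.ndarray]]:
    """(pivot atom i, pivot atom j, moving-atom index array) per rotatable bond.

    The moving side is the connected component containing j once the bond
    i-j is cut; rotating it about the i→j axis changes exactly that torsion.
    Order matches the bond order used by the rotatable-bond count.
    """
    from .chem_io import count_rotatable_bonds
    from rdkit import Chem

    rdmol = mol.rdkit_mol
    amide = rdmol.GetSubstructMatches(Chem.MolFromSmarts("[CX3](=[OX1])[NX3]"))
    amide_cn = {frozenset((m[0], m[2])) for m in amide}
    axes: list[tuple[int, int, np.ndarray]] = []
    n = rdmol.GetNumAtoms()
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for b in mol.bonds:
        adjacency[b.i].append(b.j)
        adjacency[b.j].append(b.i)
    for bond in rdmol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        deg = lambda at: sum(1 for nb in at.GetNeighbors() if nb.GetAtomicNum() > 1)
        if deg(a) < 2 or deg(b) < 2:
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_cn:
            continue
        i, j = a.GetIdx(), b.GetIdx()
        moving = _component(adjacency, start=j, blocked=(i, j))
        axes.append((i, j, np.array(sorted(moving), dtype=int)))
    if len(axes) != mol.n_tor:
        raise ChemIOError(
            f"rotatable-bond axes ({len(axes)}) inconsistent with n_tor ({mol.n_tor})"
        )
    return axes


def _component(adjacency: list[list[int]], start: int, blocked: tuple[int, int]) -> set[int]:
    i, j = blocked
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adjacency[u]:
            if (u, v) == (i, j) or (u, v) == (j, i):
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    seen.discard(i)
    return seen


def apply_pose(
    mol: LigandMolecule,
    pose: PoseGenome,
    axes: list[tuple[int, int, np.ndarray]] | None = None,
) -> np.ndarray:
    """Coordinates of ``mol`` under ``pose`` (torsions, then rigid motion).

    Torsion angles are offsets (degrees) from the stored reference
    conformation, applied in rotatable-bond order; the rigid body part then
    places the centroid of the torsioned conformation at
    ``pose.translation`` with orientation ``pose.orientation``.
    """
    coords = mol.coords
    if len(pose.torsions):
        if axes is None:
            axes = rotatable_bond_axes(mol)
        if len(axes) != len(pose.torsions):
            raise ValueError("torsion vector length does not match rotatable bonds")
        for (i, j, moving), angle in zip(axes, pose.torsions):
            if angle == 0.0:
                continue
            axis = coords[j] - coords[i]
            norm = np.linalg.norm(axis)
            if norm == 0:
                continue
            rot = Rotation.from_rotvec(np.radians(angle) * axis / norm)
            coords[moving] = rot.apply(coords[moving] - coords[j]) + coords[j]
    centroid = coords.mean(axis=0)
    rot = Rotation.from_quat(pose.orientation)
    return rot.apply(coords - centroid) + pose.translation


def _make_objective(
    mol: LigandMolecule,
    maps_or_receptor: GridMapSet | Receptor,
    params: EnergyParameters,
    tables: ParameterTables,
):
    """Return f(coords, torsions_changed) -> energy, on grids or direct."""
    from .energy import dehydration_term

    s, v, o_max = tables.hydration.arrays(mol.atom_types)
    sigma = params.sigma

    def dehydration(coords: np.ndarray) -> float:
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        g = np.exp(-d2 / (2.0 * sigma * sigma)) * v[None, :]
        np.fill_diagonal(g, 0.0)
        return float(np.dot(s, np.clip(o_max - g.sum(axis=1), 0.0, None)))

    if isinstance(maps_or_receptor, GridMapSet):
        maps = maps_or_receptor
        base_dehyd = dehydration(mol.coords)
        rigid = mol.n_tor == 0

        def objective(coords: np.ndarray) -> float:
            e_dehyd = base_dehyd if rigid else dehydration(coords)
            return grid_score(maps, mol, coords, params, tables, e_dehydration=e_dehyd)

        return objective

    receptor = maps_or_receptor

    def objective(coords: np.ndarray) -> float:
        return binding_free_energy(
            receptor, mol, params, tables, lig_coords=coords, directional=True
        ).total

    return objective


def optimize_pose(
    mol: LigandMolecule,
    maps_or_receptor: GridMapSet | Receptor,
    config: SearchConfig,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    start_translation: np.ndarray | None = None,
    start_pose: PoseGenome | None = None,
) -> tuple[PoseGenome, float]:
    """Minimize the pose energy; returns (best pose, best energy).

    Fully deterministic for identical inputs and seed.  With ``n_steps=0``
    and a given ``start_pose`` the start pose is simply scored and returned.
    The reported best energy is never worse than any start pose's energy.
    """
    params = params or default_parameters()
    tables = tables or default_tables()
    axes = rotatable_bond_axes(mol) if mol.n_tor else []
    objective = _make_objective(mol, maps_or_receptor, params, tables)

    if start_translation is None:
        if start_pose is not None:
            start_translation = start_pose.translation
        elif isinstance(maps_or_receptor, GridMapSet):
            start_translation = maps_or_receptor.box.center
        else:
            pc = maps_or_receptor.pocket_center
            start_translation = pc if pc is not None else maps_or_receptor.coords.mean(axis=0)
    start_translation = np.asarray(start_translation, float)

    rng = np.random.default_rng(int(config.seed) % (2**31))
    n_tor = mol.n_tor

    def score_of(pose: PoseGenome) -> float:
        return objective(apply_pose(mol, pose, axes))

    best_pose = (start_pose or PoseGenome.identity(start_translation, n_tor)).copy()
    best_score = score_of(best_pose)

    if config.n_steps == 0:
        return best_pose, best_score

    temps = np.geomspace(config.t_start, config.t_end, max(config.n_steps, 1))

    for k in range(config.n_starts):
        if k == 0 and start_pose is not None:
            pose = start_pose.copy()
        elif k == 0:
            pose = PoseGenome.identity(start_translation, n_tor)
        else:
            quat = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2**31)))).as_quat()
            pose = PoseGenome(
                start_translation + rng.normal(0.0, config.start_spread, 3),
                quat,
                rng.uniform(-180.0, 180.0, n_tor),
            )
        current = pose.copy()
        current_score = score_of(current)
        if current_score < best_score:
            best_pose, best_score = current.copy(), current_score
        for step in range(config.n_steps):
            cand = _propose(current, rng, config, 1.0)
            cand_score = score_of(cand)
            delta = cand_score - current_score
            if delta <= 0 or rng.random() < np.exp(-delta / temps[step]):
                current, current_score = cand, cand_score
                if current_score < best_score:
                    best_pose, best_score = current.copy(), current_score
        # greedy terminal descent with a shrinking move ladder
        current, current_score = best_pose.copy(), best_score
        for shrink in (0.5, 0.25, 0.1, 0.05, 0.02):
            for _ in range(config.greedy_rounds):
                cand = _propose(current, rng, config, shrink)
                cand_score = score_of(cand)
                if cand_score < current_score:
                    current, current_score = cand, cand_score
        if current_score < best_score:
            best_pose, best_score = current, current_score

    return best_pose, best_score


def _propose(
    pose: PoseGenome, rng: np.random.Generator, config: SearchConfig, shrink: float
) -> PoseGenome:
    cand = pose.copy()
    cand.translation = cand.translation + rng.normal(0.0, config.translation_scale * shrink, 3)
    angle = rng.normal(0.0, np.radians(config.rotation_scale * shrink))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    dq = Rotation.from_rotvec(angle * axis)
    cand.orientation = (dq * Rotation.from_quat(cand.orientation)).as_quat()
    if len(cand.torsions):
        k = int(rng.integers(len(cand.torsions)))
        cand.torsions[k] = ((cand.torsions[k] + rng.normal(0.0, config.torsion_scale * shrink)
                             + 180.0) % 360.0) - 180.0
    return PoseGenome(cand.translation, cand.orientation, cand.torsions)


def polish_pose(
    mol: LigandMolecule,
    receptor: Receptor,
    pose: PoseGenome,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    include_torsions: bool = True,
    maxiter: int = 200,
) -> tuple[PoseGenome, float]:
    """Deterministic derivative-free polish of a pose on the direct score.

    Minimizes the exact pair-sum energy over the rigid-body degrees of
    freedom (translation + incremental rotation vector) and, optionally, the
    torsions, with Powell's method.  Used to settle a grid-docked pose into
    the direct score's local minimum; fully reproducible (no randomness).
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation as R

    params = params or default_parameters()
    tables = tables or default_tables()
    axes = rotatable_bond_axes(mol) if mol.n_tor else []
    q0 = R.from_quat(pose.orientation)
    n_tor = len(pose.torsions) if include_torsions else 0

    def unpack(x: np.ndarray) -> PoseGenome:
        q = (R.from_rotvec(x[3:6]) * q0).as_quat()
        torsions = x[6 : 6 + n_tor] if n_tor else pose.torsions
        return PoseGenome(x[:3], q, torsions)

    def f(x: np.ndarray) -> float:
        p = unpack(x)
        return binding_free_energy(
            receptor, mol, params, tables, lig_coords=apply_pose(mol, p, axes)
        ).total

    x0 = np.concatenate(
        [pose.translation, np.zeros(3)]
        + ([np.asarray(pose.torsions, float)] if n_tor else [])
    )
    res = minimize(
        f, x0, method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": maxiter},
    )
    return unpack(res.x), float(res.fun)


def local_refine(
    mol: LigandMolecule,
    maps_or_receptor: GridMapSet | Receptor,
    pose: PoseGenome,
    config: SearchConfig | None = None,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
) -> tuple[PoseGenome, float]:
    """Deterministic greedy descent from a given pose (no annealing phase).

    Runs only the shrinking-ladder improvement loop, so the result stays in
    the basin of the start pose; useful for settling a constructed pose
    into its local energy minimum.
    """
    config = config or SearchConfig()
    params = params or default_parameters()
    tables = tables or default_tables()
    axes = rotatable_bond_axes(mol) if mol.n_tor else []
    objective = _make_objective(mol, maps_or_receptor, params, tables)
    rng = np.random.default_rng(int(config.seed) % (2**31))
    current = pose.copy()
    current_score = objective(apply_pose(mol, current, axes))
    for shrink in (1.0, 0.5, 0.25, 0.1, 0.05, 0.02):
        for _ in range(config.greedy_rounds):
            cand = _propose(current, rng, config, shrink)
            cand_score = objective(apply_pose(mol, cand, axes))
            if cand_score < current_score:
                current, current_score = cand, cand_score
    return current, current_score


def rescore_direct(
    receptor: Receptor,
    mol: LigandMolecule,
    pose: PoseGenome | None,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
) -> ScoreBreakdown:
    """Exact pair-sum ΔG_b^aq of a pose, with the angular E(t) factor.

    This, not the grid score, is the value every screening filter consumes.
    ``pose=None`` scores the ligand at its stored coordinates.
    """
    coords = apply_pose(mol, pose) if pose is not None else mol.coords
    return binding_free_energy(
        receptor, mol, params, tables, lig_coords=coords, directional=True
    )
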