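"""Precomputed affinity grid maps and trilinear pose scoring.

A :class:`GridMapSet` stores, on a regular lattice over the receptor, one
potential array per probe atom type (the weighted 12-6 / 12-10 interaction
of a probe atom of that type with all receptor atoms) plus an electrostatic
potential array per unit probe charge.  Scoring a pose then costs one
trilinear interpolation per ligand atom instead of a full pair sum, which is
what makes screening hundreds of molecules tractable.

Hydrogen-bond wells on the maps are stored at their E(t)=1 upper bound:
a probe type carries no donor-hydrogen vector, so the angular factor can
only be applied in direct rescoring of final poses.

A whole-receptor box (see :func:`whole_domain_box`) supports scanning the
entire domain for peripheral binding sites away from the orthosteric pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import LigandMolecule, Receptor
from .energy import dehydration_term, sigmoidal_dielectric, torsion_penalty
from .params import EnergyParameters, ParameterTables, default_parameters, default_tables

__all__ = [
    "GridBox",
    "GridMapSet",
    "build_grid_maps",
    "interpolate",
    "whole_domain_box",
    "peripheral_site_scan",
    "OUT_OF_BOX_PENALTY",
    "MAP_VALUE_CAP",
]

#: Energy (kcal/mol) charged to every ligand atom outside the grid box, so
#: that pose searches are repelled back inside.
OUT_OF_BOX_PENALTY = 1.0e4

#: Upper clamp applied to stored map values; keeps the repulsive wall finite
#: on nodes that sit on top of receptor atoms.
MAP_VALUE_CAP = 1.0e5


@dataclass(frozen=True)
class GridBox:
    origin: np.ndarray  # Å, position of node (0,0,0)
    spacing: float  # Å
    npts: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.npts):
            raise ValueError("need at least 2 points per axis")

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.npts) - 1)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.origin + self.upper)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.npts[k]) for k in range(3)
        )

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape (nx*ny*nz, 3), x fastest last (C order)."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.origin - 1e-9) & (p <= self.upper + 1e-9), axis=1)


@dataclass
class GridMapSet:
    box: GridBox
    probe_maps: dict[str, np.ndarray]  # type -> (nx,ny,nz) kcal/mol per probe atom
    elec_map: np.ndarray  # (nx,ny,nz) kcal/(mol·e)
    provenance: dict = field(default_factory=dict)

    @property
    def probe_types(self) -> list[str]:
        return sorted(self.probe_maps)


def whole_domain_box(receptor: Receptor, margin: float = 5.0, spacing: float = 1.0) -> GridBox:
    """Axis-aligned bounding box of all receptor atoms plus ``margin``, snapped.

    The origin is snapped *down* and the far corner *up* to integer multiples
    of ``spacing``, so the box always contains every receptor atom plus the
    full margin.
    """
    coords = receptor.coords
    if coords.size == 0:
        raise ValueError("receptor has no atoms")
    lo = np.floor((coords.min(axis=0) - margin) / spacing) * spacing
    hi = np.ceil((coords.max(axis=0) + margin) / spacing) * spacing
    npts = tuple(int(round((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    npts = tuple(max(2, n) for n in npts)
    return GridBox(origin=lo, spacing=spacing, npts=npts)


def pocket_box(center: np.ndarray, half_width: float = 8.0, spacing: float = 0.375) -> GridBox:
    """Cubic box of ±half_width around a pocket center, snapped to spacing."""
    n_half = int(np.ceil(half_width / spacing))
    npts = 2 * n_half + 1
    origin = np.asarray(center, float) - n_half * spacing
    return GridBox(origin=origin, spacing=spacing, npts=(npts, npts, npts))


def build_grid_maps(
    receptor: Receptor,
    box: GridBox,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    probe_types: list[str] | None = None,
    chunk: int = 20000,
) -> GridMapSet:
    """Precompute per-probe-type and electrostatic maps over ``box``.

    Each node holds the weighted interaction energy of a single probe atom
    with every receptor atom within the nonbonded cutoff (12-6 wells, or the
    E(t)=1 12-10 well for polar-hydrogen/acceptor pairs) and, separately,
    the electrostatic potential per unit probe charge.  Values are clamped
    at :data:`MAP_VALUE_CAP`.
    """
    import logging

    params = params or default_parameters()
    tables = tables or default_tables()
    probe_types = probe_types or tables.pair.types
    rec_coords = receptor.coords
    rec_types = receptor.atom_types
    rec_charges = receptor.charges

    nodes = box.nodes()
    near = np.zeros(len(rec_coords), dtype=bool)
    lo, hi = box.origin - params.nonbonded_cutoff, box.upper + params.nonbonded_cutoff
    near = np.all((rec_coords >= lo) & (rec_coords <= hi), axis=1)
    if not near.any():
        logging.getLogger(__name__).warning(
            "no receptor atom within cutoff of the grid box; maps will be zero"
        )

    n_nodes = nodes.shape[0]
    probe_flat = {t: np.zeros(n_nodes) for t in probe_types}
    elec_flat = np.zeros(n_nodes)
    a_mat, b_mat, hb_mat = tables.pair.matrices(probe_types, rec_types)

    for start in range(0, n_nodes, chunk):
        block = nodes[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - rec_coords[None, :, :], axis=2)
        within = d <= params.nonbonded_cutoff
        d_eff = np.maximum(d, params.inner_clamp)
        inv2 = 1.0 / (d_eff * d_eff)
        inv6 = inv2**3
        inv10 = inv2**5
        inv12 = inv6 * inv6
        eps = sigmoidal_dielectric(d_eff, params.dielectric_constants)
        coul = params.coulomb_constant * rec_charges[None, :] / (eps * d_eff)
        elec_flat[start : start + chunk] = params.w_elec * np.sum(
            np.where(within, coul, 0.0), axis=1
        )
        for p, t in enumerate(probe_types):
            hb = hb_mat[p][None, :]
            e = np.where(
                hb,
                params.w_hbond * (a_mat[p][None, :] * inv12 - b_mat[p][None, :] * inv10),
                params.w_vdw * (a_mat[p][None, :] * inv12 - b_mat[p][None, :] * inv6),
            )
            probe_flat[t][start : start + chunk] = np.sum(
                np.where(within, e, 0.0), axis=1
            )

    shape = box.npts
    probe_maps = {
        t: np.minimum(v.reshape(shape), MAP_VALUE_CAP) for t, v in probe_flat.items()
    }
    elec_map = np.clip(elec_flat.reshape(shape), -MAP_VALUE_CAP, MAP_VALUE_CAP)
    provenance = {
        "receptor": receptor.name,
        "params_hash": tables.provenance_hash(),
        "spacing": box.spacing,
        "npts": list(box.npts),
    }
    return GridMapSet(box=box, probe_maps=probe_maps, elec_map=elec_map, provenance=provenance)


def _trilinear(box: GridBox, grid: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``grid`` at ``points`` (assumed inside)."""
    f = (points - box.origin) / box.spacing
    near = np.round(f)
    snap = np.abs(f - near) < 1e-9  # exact node values survive float round-off
    f = np.where(snap, near, f)
    f = np.clip(f, 0.0, np.array(box.npts) - 1.0)
    i0 = np.floor(f).astype(int)
    i0 = np.minimum(i0, np.array(box.npts) - 2)  # top edge uses w = 1 exactly
    w = f - i0
    out = np.zeros(len(points))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                weight = (
                    (w[:, 0] if dx else 1 - w[:, 0])
                    * (w[:, 1] if dy else 1 - w[:, 1])
                    * (w[:, 2] if dz else 1 - w[:, 2])
                )
                out += weight * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def interpolate(
    maps: GridMapSet, point: np.ndarray, probe_type: str, charge: float = 0.0
) -> float:
    """Interpolated energy of one probe atom at ``point`` (kcal/mol).

    Points outside the box return :data:`OUT_OF_BOX_PENALTY`.  At a grid
    node the interpolation reproduces the stored node value exactly.
    """
    if probe_type not in maps.probe_maps:
        raise KeyError(f"no grid map for probe type {probe_type!r}")
    point = np.asarray(point, float)
    if not maps.box.contains(point)[0]:
        return OUT_OF_BOX_PENALTY
    p = point[None, :]
    val = _trilinear(maps.box, maps.probe_maps[probe_type], p)[0]
    if charge:
        val += charge * _trilinear(maps.box, maps.elec_map, p)[0]
    return float(val)


def grid_score(
    maps: GridMapSet,
    mol: LigandMolecule,
    lig_coords: np.ndarray,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
    e_dehydration: float | None = None,
) -> float:
    """Total grid-based ΔG of a posed ligand (kcal/mol).

    Sum of interpolated probe-map and electrostatic contributions per atom,
    plus the torsional penalty and the (conformation-only) dehydration term.
    ``e_dehydration`` may be passed in when the conformation is rigid so the
    term is not recomputed per pose.
    """
    params = params or default_parameters()
    tables = tables or default_tables()
    lig_coords = np.asarray(lig_coords, float)
    inside = maps.box.contains(lig_coords)
    total = float(np.sum(~inside)) * OUT_OF_BOX_PENALTY
    if inside.any():
        pts = lig_coords[inside]
        types = [t for t, ok in zip(mol.atom_types, inside) if ok]
        charges = mol.charges[inside]
        for t in set(types):
            sel = np.array([x == t for x in types])
            total += float(np.sum(_trilinear(maps.box, maps.probe_maps[t], pts[sel])))
        total += float(np.sum(charges * _trilinear(maps.box, maps.elec_map, pts)))
    total += torsion_penalty(mol.n_tor, params.w_tor)
    if e_dehydration is None:
        e_dehydration = dehydration_term(mol.with_coords(lig_coords), tables, params.sigma)
    return total + e_dehydration


def peripheral_site_scan(
    receptor: Receptor,
    mol: LigandMolecule,
    maps: GridMapSet,
    search_config=None,
    lattice_stride: float = 4.0,
    cluster_radius: float = 3.0,
    exclude_center: np.ndarray | None = None,
    exclude_radius: float = 0.0,
    params: EnergyParameters | None = None,
    tables: ParameterTables | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Scan the whole grid box for sites that bind ``mol`` with ΔG < 0.

    Pose searches are started from a coarse lattice of points covering the
    box; converged poses with negative total grid score are clustered by
    center distance and the best representative of each cluster is returned,
    sorted by ascending ΔG.  Sites within ``exclude_radius`` of
    ``exclude_center`` (e.g. the annotated orthosteric pocket) are dropped.
    An empty list means no peripheral site stabilizes the ligand.
    """
    from .search import SearchConfig, optimize_pose

    config = search_config or SearchConfig(seed=7, n_starts=1, n_steps=120)
    params = params or default_parameters()
    tables = tables or default_tables()

    lo, hi = maps.box.origin, maps.box.upper
    axes = [np.arange(lo[k] + lattice_stride / 2, hi[k], lattice_stride) for k in range(3)]
    hits: list[tuple[np.ndarray, float]] = []
    for idx, start in enumerate(
        np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    ):
        cfg = SearchConfig(
            seed=config.seed + idx,
            n_starts=1,
            n_steps=config.n_steps,
            translation_scale=config.translation_scale,
            rotation_scale=config.rotation_scale,
            torsion_scale=config.torsion_scale,
        )
        pose, score = optimize_pose(
            mol, maps, cfg, params=params, tables=tables, start_translation=start
        )
        if score < 0:
            hits.append((pose.translation.copy(), float(score)))
    hits.sort(key=lambda h: h[1])
    reps: list[tuple[np.ndarray, float]] = []
    for center, score in hits:
        if exclude_center is not None and exclude_radius > 0:
            if np.linalg.norm(center - exclude_center) < exclude_radius:
                continue
        if all(np.linalg.norm(center - c) > cluster_radius for c, _ in reps):
            reps.append((center, score))
    return reps


# ---------------------------------------------------------------------------
# plain-text serialization (AutoDock-style .map dialect)
# ---------------------------------------------------------------------------

def write_map(maps: GridMapSet, probe_type: str, path) -> None:
    """Write one probe map in an AutoDock-flavoured plain-text .map format."""
    from pathlib import Path

    grid = maps.elec_map if probe_type == "e" else maps.probe_maps[probe_type]
    box = maps.box
    header = [
        f"GRID_PARAMETER_FILE {maps.provenance.get('receptor', '')}",
        f"SPACING {box.spacing:g}",
        f"NELEMENTS {box.npts[0] - 1} {box.npts[1] - 1} {box.npts[2] - 1}",
        f"CENTER {box.center[0]:.4f} {box.center[1]:.4f} {box.center[2]:.4f}",
        f"PROBE {probe_type}",
    ]
    # AutoDock map order: x fastest, then y, then z
    values = grid.transpose(2, 1, 0).reshape(-1)
    body = "\n".join(f"{v:.6g}" for v in values)
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


def read_map(path) -> tuple[GridBox, np.ndarray, str]:
    """Read a plain-text map written by :func:`write_map`."""
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for k, line in enumerate(lines):
        key = line.split(" ", 1)[0]
        if key in ("GRID_PARAMETER_FILE", "SPACING", "NELEMENTS", "CENTER", "PROBE"):
            meta[key] = line.split(" ", 1)[1] if " " in line else ""
            body_start = k + 1
        else:
            break
    spacing = float(meta["SPACING"])
    nel = [int(x) for x in meta["NELEMENTS"].split()]
    npts = tuple(n + 1 for n in nel)
    center = np.array([float(x) for x in meta["CENTER"].split()])
    origin = center - spacing * (np.array(npts) - 1) / 2.0
    values = np.array([float(x) for x in lines[body_start:] if x.strip()])
    grid = values.reshape(npts[2], npts[1], npts[0]).transpose(2, 1, 0)
    return GridBox(origin, spacing, npts), grid, meta.get("PROBE", "")
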