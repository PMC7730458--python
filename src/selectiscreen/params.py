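"""Externalized parameters of the binding free energy function.

Every coefficient of the score — the four term weights, the sigmoidal
dielectric constants, the Gaussian occupancy width sigma, the 12-6 / 12-10
pair potentials and the atomic hydration parameters (S, V, O^max) — lives in
these tables and can be loaded from plain-text files (TSV for the tables,
YAML for scalars), so a refit never touches code.

The shipped defaults are:

* term weights: the classic free-energy calibration of the docking-tool
  family this score extends (W_vdW 0.1485, W_hbond 0.0656, W_elec 0.1146,
  W_tor 0.3113);
* pair potentials derived from AMBER-style per-type (Rmin, epsilon) via
  Lorentz-Berthelot-like combination, with 12-10 wells for polar-hydrogen /
  acceptor pairs;
* an *illustrative* hydration table for {C, C.ar, N, O, S, P, H, HD,
  halogens}: the solvent-contact model publishes per-type S/V/O^max fitted on
  experimental hydration free energies, and users supplying a fitted table
  simply replace the TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "EnergyParameters",
    "PairPotentialTable",
    "HydrationParamTable",
    "ParameterTables",
    "VdwType",
    "default_parameters",
    "default_tables",
    "load_parameters",
]


@dataclass(frozen=True)
class EnergyParameters:
    """Scalar knobs of the score.

    dielectric_constants are (A, B, k, lam) of the sigmoidal screening
    function eps(r) = A + B / (1 + k * exp(-lam * B * r)); the defaults give
    eps(0) ~ 1.35 and the bulk-water limit A + B = 78.4.
    """

    w_vdw: float = 0.1485
    w_hbond: float = 0.0656
    w_elec: float = 0.1146
    w_tor: float = 0.3113
    coulomb_constant: float = 332.0  # kcal*A/(mol*e^2)
    dielectric_constants: tuple[float, float, float, float] = (
        -8.5525, 86.9525, 7.7839, 0.003627,
    )
    sigma: float = 3.5  # Angstrom; Gaussian width of the occupancy envelope
    hbond_angle_cutoff: float = 90.0  # degrees
    nonbonded_cutoff: float = 12.0  # Angstrom
    inner_clamp: float = 0.5  # Angstrom; distances below are clamped

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for w in (self.w_vdw, self.w_hbond, self.w_elec, self.w_tor):
            if not math.isfinite(w):
                raise ValueError("term weights must be finite")
        a, b, k, lam = self.dielectric_constants
        if a + b / (1.0 + k) <= 0 or a + b <= 0:
            raise ValueError("dielectric function must be positive for all r >= 0")


@dataclass(frozen=True)
class VdwType:
    """Per-type Lennard-Jones source parameters (combined into pair tables)."""

    rmin_half: float  # Angstrom, half the pair equilibrium distance for like pairs
    epsilon: float  # kcal/mol well depth for like pairs
    is_acceptor: bool = False  # participates in 12-10 wells opposite HD
    hb_r0: float = 1.9  # Angstrom, H...acceptor equilibrium distance
    hb_eps: float = 5.0  # kcal/mol, 12-10 well depth


# AutoDock/AMBER-flavoured per-type van der Waals sources.
_DEFAULT_VDW: dict[str, VdwType] = {
    "C": VdwType(2.00, 0.150),
    "C.ar": VdwType(2.00, 0.150),
    "N": VdwType(1.75, 0.160, is_acceptor=True, hb_r0=1.90, hb_eps=5.0),
    "O": VdwType(1.60, 0.200, is_acceptor=True, hb_r0=1.90, hb_eps=5.0),
    "S": VdwType(2.00, 0.200, is_acceptor=True, hb_r0=2.50, hb_eps=1.0),
    "P": VdwType(2.10, 0.200),
    "F": VdwType(1.545, 0.080),
    "Cl": VdwType(2.045, 0.276),
    "Br": VdwType(2.165, 0.389),
    "I": VdwType(2.36, 0.550),
    "H": VdwType(1.00, 0.020),
    "HD": VdwType(1.00, 0.020),
}

# Illustrative solvent-contact hydration parameters per atom type:
# S in kcal/(mol*A^3), V in A^3, O_max in A^3.  Positive S marks hydrophilic
# atoms (dehydration penalty on binding); small negative S marks hydrophobes.
_DEFAULT_HYDRATION: dict[str, tuple[float, float, float]] = {
    "C": (-0.0010, 20.6, 220.0),
    "C.ar": (-0.0010, 18.0, 210.0),
    "N": (0.0080, 13.0, 190.0),
    "O": (0.0090, 11.0, 180.0),
    "S": (0.0015, 24.0, 230.0),
    "P": (0.0030, 25.0, 230.0),
    "F": (0.0025, 15.0, 190.0),
    "Cl": (0.0012, 26.0, 230.0),
    "Br": (0.0009, 30.0, 240.0),
    "I": (0.0006, 36.0, 250.0),
    "H": (0.0000, 3.0, 110.0),
    "HD": (0.0060, 2.0, 100.0),
}


class PairPotentialTable:
    """Symmetric (type_i, type_j) -> (A, B) 12-6 or (C, D) 12-10 coefficients.

    For a 12-6 pair, E(r) = A/r^12 - B/r^6 with minimum -eps at
    r = (2A/B)^(1/6).  For a 12-10 hydrogen-bonding pair (flagged
    ``is_hbond_pair``), E(r) = C/r^12 - D/r^10 with minimum -eps at
    r = sqrt(6C/5D).
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], tuple[float, float, bool]] = {}

    @staticmethod
    def _key(ti: str, tj: str) -> tuple[str, str]:
        return (ti, tj) if ti <= tj else (tj, ti)

    def set_pair(self, ti: str, tj: str, a: float, b: float, is_hbond: bool = False) -> None:
        if a <= 0 or b <= 0:
            raise ValueError(f"pair coefficients for ({ti},{tj}) must be positive")
        self._entries[self._key(ti, tj)] = (float(a), float(b), bool(is_hbond))

    def get(self, ti: str, tj: str) -> tuple[float, float, bool]:
        try:
            return self._entries[self._key(ti, tj)]
        except KeyError:
            raise KeyError(f"no pair potential for types ({ti}, {tj})") from None

    def is_hbond_pair(self, ti: str, tj: str) -> bool:
        return self.get(ti, tj)[2]

    @property
    def types(self) -> list[str]:
        seen: set[str] = set()
        for ti, tj in self._entries:
            seen.update((ti, tj))
        return sorted(seen)

    def matrices(
        self, types_i: Iterable[str], types_j: Iterable[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(A|C, B|D, is_hbond) arrays for the cross product of two type lists."""
        ti = list(types_i)
        tj = list(types_j)
        a = np.empty((len(ti), len(tj)))
        b = np.empty((len(ti), len(tj)))
        hb = np.empty((len(ti), len(tj)), dtype=bool)
        cache: dict[tuple[str, str], tuple[float, float, bool]] = {}
        for p, x in enumerate(ti):
            for q, y in enumerate(tj):
                key = self._key(x, y)
                if key not in cache:
                    cache[key] = self.get(x, y)
                a[p, q], b[p, q], hb[p, q] = cache[key]
        return a, b, hb

    @classmethod
    def from_vdw_types(cls, vdw: dict[str, VdwType] | None = None) -> "PairPotentialTable":
        """Build the full pair table from per-type sources by combination rules."""
        vdw = dict(vdw or _DEFAULT_VDW)
        table = cls()
        types = sorted(vdw)
        for i, ti in enumerate(types):
            for tj in types[i:]:
                pi, pj = vdw[ti], vdw[tj]
                donor_acceptor = (ti == "HD" and pj.is_acceptor) or (
                    tj == "HD" and pi.is_acceptor
                )
                if donor_acceptor:
                    acc = pj if pj.is_acceptor else pi
                    r0, eps = acc.hb_r0, acc.hb_eps
                    c = 5.0 * eps * r0**12
                    d = 6.0 * eps * r0**10
                    table.set_pair(ti, tj, c, d, is_hbond=True)
                else:
                    rij = pi.rmin_half + pj.rmin_half
                    eps = math.sqrt(pi.epsilon * pj.epsilon)
                    a = eps * rij**12
                    b = 2.0 * eps * rij**6
                    table.set_pair(ti, tj, a, b, is_hbond=False)
        return table

    # -- plain-text round trip -------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        lines = ["type_i\ttype_j\tA_or_C\tB_or_D\tis_hbond_pair"]
        for (ti, tj), (a, b, hb) in sorted(self._entries.items()):
            lines.append(f"{ti}\t{tj}\t{a!r}\t{b!r}\t{int(hb)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairPotentialTable":
        table = cls()
        rows = Path(path).read_text().splitlines()
        for line in rows[1:]:
            if not line.strip():
                continue
            ti, tj, a, b, hb = line.split("\t")
            table.set_pair(ti, tj, float(a), float(b), bool(int(hb)))
        return table


class HydrationParamTable:
    """atom type -> (S, V, O_max) of the solvent-contact dehydration term."""

    def __init__(self, entries: dict[str, tuple[float, float, float]] | None = None):
        self._entries: dict[str, tuple[float, float, float]] = {}
        for t, (s, v, omax) in (entries or {}).items():
            self.set_type(t, s, v, omax)

    def set_type(self, atom_type: str, s: float, v: float, o_max: float) -> None:
        if v <= 0 or o_max <= 0:
            raise ValueError(f"V and O_max for {atom_type!r} must be positive")
        self._entries[atom_type] = (float(s), float(v), float(o_max))

    def get(self, atom_type: str) -> tuple[float, float, float]:
        try:
            return self._entries[atom_type]
        except KeyError:
            raise KeyError(f"no hydration parameters for type {atom_type!r}") from None

    def arrays(self, types: Iterable[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        types = list(types)
        missing = sorted({t for t in types if t not in self._entries})
        if missing:
            raise KeyError(f"no hydration parameters for types {missing}")
        s = np.array([self._entries[t][0] for t in types])
        v = np.array([self._entries[t][1] for t in types])
        o = np.array([self._entries[t][2] for t in types])
        return s, v, o

    @property
    def types(self) -> list[str]:
        return sorted(self._entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["atom_type\tS\tV\tO_max"]
        for t, (s, v, o) in sorted(self._entries.items()):
            lines.append(f"{t}\t{s!r}\t{v!r}\t{o!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HydrationParamTable":
        table = cls()
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            t, s, v, o = line.split("\t")
            table.set_type(t, float(s), float(v), float(o))
        return table


@dataclass
class ParameterTables:
    """Bundle of the two lookup tables consumed by the scoring routines."""

    pair: PairPotentialTable
    hydration: HydrationParamTable

    def provenance_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for key, val in sorted(self.pair._entries.items()):
            h.update(repr((key, val)).encode())
        for key, val in sorted(self.hydration._entries.items()):
            h.update(repr((key, val)).encode())
        return h.hexdigest()[:16]


def default_parameters(**overrides) -> EnergyParameters:
    return replace(EnergyParameters(), **overrides) if overrides else EnergyParameters()


def default_tables() -> ParameterTables:
    return ParameterTables(
        pair=PairPotentialTable.from_vdw_types(),
        hydration=HydrationParamTable(_DEFAULT_HYDRATION),
    )


def load_parameters(path: str | Path) -> EnergyParameters:
    """Load scalar parameters from a small YAML file (missing keys -> defaults)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if "dielectric_constants" in data:
        data["dielectric_constants"] = tuple(data["dielectric_constants"])
    return default_parameters(**data)
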