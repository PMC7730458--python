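"""The binding free energy function: term primitives and the full pose score."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selectiscreen.energy import (
    HBondGeometry,
    binding_free_energy,
    coulomb_energy,
    dehydration_term,
    directionality_weight,
    hb_12_10,
    ligand_occupancy,
    lj_12_6,
    sigmoidal_dielectric,
    torsion_penalty,
)
from selectiscreen.params import (
    EnergyParameters,
    HydrationParamTable,
    ParameterTables,
    default_parameters,
    default_tables,
)

from .conftest import toy_ligand, toy_receptor


class TestLJ126:
    def test_vanishes_at_long_range(self):
        assert abs(lj_12_6(50.0, 1.0, 1.0)) < 1e-6

    def test_minimum_location_and_depth_closed_form(self):
        # d/dr (A r^-12 - B r^-6) = 0 at r = (2A/B)^(1/6), E = -B^2/(4A)
        for a, b in [(1.0, 1.0), (3.7e5, 210.0), (12.0, 5.0)]:
            r_min = (2 * a / b) ** (1 / 6)
            assert lj_12_6(r_min, a, b) == pytest.approx(-b * b / (4 * a), rel=1e-12)
            for dr in (-1e-3, 1e-3):
                assert lj_12_6(r_min + dr, a, b) > lj_12_6(r_min, a, b)

    def test_unit_coefficients_min(self):
        assert lj_12_6(2 ** (1 / 6), 1.0, 1.0) == pytest.approx(-0.25, rel=1e-12)

    def test_inner_clamp_keeps_finite(self):
        assert lj_12_6(1e-6, 1.0, 1.0) == lj_12_6(0.5, 1.0, 1.0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            lj_12_6(0.0, 1.0, 1.0)


class TestDirectionality:
    @pytest.mark.parametrize("t,expected", [(0.0, 1.0), (90.0, 0.0), (30.0, 0.75),
                                            (120.0, 0.0), (60.0, 0.25)])
    def test_cos_square_ramp(self, t, expected):
        assert directionality_weight(t) == pytest.approx(expected, abs=1e-12)

    def test_deviation_angle_geometry(self):
        # collinear D-H...A is the ideal geometry (t = 0)
        g = HBondGeometry(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.9, 0, 0]))
        assert g.deviation_angle == pytest.approx(0.0, abs=1e-9)
        g = HBondGeometry(np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1.9, 0]))
        assert g.deviation_angle == pytest.approx(90.0, abs=1e-9)


class TestHB1210:
    def test_perpendicular_geometry_zero(self):
        assert hb_12_10(1.9, 1.0, 1.0, t=90.0) == 0.0

    def test_minimum_at_sqrt_six_fifths(self):
        # d/dr (C r^-12 - D r^-10) = 0 at r = sqrt(6C/5D)
        for c, d in [(1.0, 1.0), (5.5e4, 2.2e4), (3.0, 7.0)]:
            r_min = math.sqrt(6 * c / (5 * d))
            e_min = hb_12_10(r_min, c, d, t=0.0)
            for dr in (-1e-3, 1e-3):
                assert hb_12_10(r_min + dr, c, d, t=0.0) > e_min

    def test_linear_in_coefficients(self):
        assert hb_12_10(2.0, 2.0, 2.0, t=0.0) == pytest.approx(
            2 * hb_12_10(2.0, 1.0, 1.0, t=0.0), rel=1e-12
        )


class TestDielectric:
    def test_contact_limit(self):
        # eps(0) = A + B/(1+k) with the screened-dielectric reference constants
        assert sigmoidal_dielectric(0.0) == pytest.approx(1.3466, abs=1e-3)

    def test_bulk_limit(self):
        assert sigmoidal_dielectric(100.0) == pytest.approx(78.4, abs=1.0)

    @given(st.floats(0.0, 80.0), st.floats(0.0, 80.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert sigmoidal_dielectric(hi) >= sigmoidal_dielectric(lo) - 1e-12


class TestCoulomb:
    def test_zero_charge_gives_zero(self):
        assert coulomb_energy(0.0, 0.7, 3.0) == 0.0

    def test_sign_convention(self):
        assert coulomb_energy(0.5, 0.5, 3.0) > 0
        assert coulomb_energy(0.5, -0.5, 3.0) < 0

    def test_hand_evaluation(self):
        # 332 * q_i q_j / (eps(r) * r) evaluated independently
        eps = sigmoidal_dielectric(3.0)
        expected = 332.0 * 0.25 / (eps * 3.0)
        assert coulomb_energy(0.5, 0.5, 3.0) == pytest.approx(expected, rel=1e-12)


class TestTorsionPenalty:
    def test_zero_rotors(self):
        assert torsion_penalty(0, 0.3113) == 0.0

    def test_linearity_and_product(self):
        assert torsion_penalty(10, 0.3113) == pytest.approx(2 * torsion_penalty(5, 0.3113))
        assert torsion_penalty(3, 0.3113) == pytest.approx(0.9339, abs=1e-10)


class TestDehydration:
    def test_isolated_atom_zero_occupancy(self, tables):
        mol = toy_ligand(["O"], [[0.0, 0.0, 0.0]])
        assert ligand_occupancy(0, mol, sigma=3.5, tables=tables) == 0.0

    def test_two_atom_occupancy_at_sigma(self, tables):
        mol = toy_ligand(["O", "C"], [[0, 0, 0], [3.5, 0, 0]])
        _, v, _ = tables.hydration.arrays(["C"])
        expected = float(v[0]) * math.exp(-0.5)
        assert ligand_occupancy(0, mol, 3.5, tables) == pytest.approx(expected, rel=1e-12)

    def test_full_overlap_gives_full_volume(self, tables):
        mol = toy_ligand(["O", "C"], [[0, 0, 0], [0, 0, 0]])
        _, v, _ = tables.hydration.arrays(["C"])
        assert ligand_occupancy(0, mol, 3.5, tables) == pytest.approx(float(v[0]))

    def test_single_atom_term_is_s_times_omax(self, tables):
        mol = toy_ligand(["O"], [[1.0, 2.0, 3.0]])
        s, _, o_max = tables.hydration.arrays(["O"])
        assert dehydration_term(mol, tables) == pytest.approx(float(s[0] * o_max[0]))

    def test_zero_s_gives_zero(self):
        hyd = HydrationParamTable({t: (0.0, v, o) for t, (s, v, o) in
                                   zip(["C", "O"], [(0.1, 20.0, 200.0), (0.2, 11.0, 180.0)])})
        tab = ParameterTables(pair=default_tables().pair, hydration=hyd)
        mol = toy_ligand(["C", "O"], [[0, 0, 0], [1.4, 0, 0]])
        assert dehydration_term(mol, tab) == 0.0

    def test_matches_brute_force_double_loop(self, tables):
        rng = np.random.default_rng(3)
        types = ["O", "N", "C", "HD", "C.ar"]
        coords = rng.normal(0.0, 2.0, (5, 3))
        mol = toy_ligand(types, coords)
        sigma = 3.5
        total = 0.0
        for i, ti in enumerate(types):
            s_i, _, omax_i = tables.hydration.get(ti)
            occ = 0.0
            for j, tj in enumerate(types):
                if i == j:
                    continue
                _, v_j, _ = tables.hydration.get(tj)
                r2 = float(np.sum((coords[i] - coords[j]) ** 2))
                occ += v_j * math.exp(-r2 / (2 * sigma * sigma))
            total += s_i * max(0.0, omax_i - occ)
        assert dehydration_term(mol, tables, sigma) == pytest.approx(total, abs=1e-10)

    def test_pure_ligand_property(self, tables, planted, receptor_pair):
        """Moving the receptor cannot change the dehydration term at all."""
        mut, _ = receptor_pair
        binder, _ = planted
        e1 = binding_free_energy(mut, binder).e_dehydration
        shifted = toy_receptor(
            mut.atom_types, mut.coords + 17.0, mut.charges
        )
        e2 = binding_free_energy(shifted, binder).e_dehydration
        assert e1 == e2  # bit-identical


def _naive_score(receptor, mol, params, tables, directional=False):
    """Unvectorized reference: double loop over all receptor-ligand pairs."""
    from selectiscreen.energy import _directionality_matrix

    e_vdw = e_hb = e_el = 0.0
    lig_coords = mol.coords
    et = (_directionality_matrix(receptor, mol, lig_coords, params)
          if directional else None)
    for i, ra in enumerate(receptor.atoms):
        for j, la in enumerate(mol.atoms):
            r = float(np.linalg.norm(ra.coords - la.coords))
            if r > params.nonbonded_cutoff:
                continue
            r_eff = max(r, params.inner_clamp)
            a, b, is_hb = tables.pair.get(ra.atom_type, la.atom_type)
            if is_hb:
                w = et[i, j] if et is not None else 1.0
                e_hb += w * (a / r_eff**12 - b / r_eff**10)
            else:
                e_vdw += a / r_eff**12 - b / r_eff**6
            eps = sigmoidal_dielectric(r_eff, params.dielectric_constants)
            e_el += params.coulomb_constant * ra.partial_charge * la.partial_charge / (eps * r_eff)
    total = (params.w_vdw * e_vdw + params.w_hbond * e_hb + params.w_elec * e_el
             + params.w_tor * mol.n_tor + dehydration_term(mol, tables, params.sigma))
    return total


class TestBindingFreeEnergy:
    def test_separation_limit(self, params, tables):
        rec = toy_receptor(["C", "O", "N"], [[0, 0, 0], [2, 0, 0], [0, 2, 0]],
                           charges=[0.1, -0.3, -0.2])
        mol = toy_ligand(["C", "O"], [[100, 0, 0], [101, 0, 0]], charges=[0.05, -0.3])
        sb = binding_free_energy(rec, mol, params, tables)
        assert sb.e_vdw == 0.0 and sb.e_hbond == 0.0 and sb.e_elec == 0.0
        assert sb.total == pytest.approx(sb.e_tor + sb.e_dehydration)

    def test_breakdown_sums_to_total(self, params, tables, receptor_pair, planted):
        mut, _ = receptor_pair
        binder, _ = planted
        sb = binding_free_energy(mut, binder, params, tables)
        parts = sb.e_vdw + sb.e_hbond + sb.e_elec + sb.e_tor + sb.e_dehydration
        assert sb.total == pytest.approx(parts, abs=1e-9)

    def test_matches_naive_double_loop_small_fixture(self, params, tables):
        rec = toy_receptor(["C", "O", "N", "HD", "C"],
                           [[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0], [1.5, 1.5, 2]],
                           charges=[0.1, -0.4, -0.35, 0.25, 0.0])
        mol = toy_ligand(["N", "C"], [[1.5, 1.5, 4.0], [1.5, 3.0, 4.5]],
                         charges=[-0.3, 0.1])
        got = binding_free_energy(rec, mol, params, tables, directional=False).total
        want = _naive_score(rec, mol, params, tables, directional=False)
        assert got == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("trial", range(10))
    def test_oracle_equivalence_random_fixtures(self, trial, params, tables):
        """Vectorized scoring equals the naive double loop on random toys."""
        rng = np.random.default_rng(100 + trial)
        types = ["C", "C.ar", "N", "O", "S", "HD", "H"]
        nr, nl = rng.integers(3, 8), rng.integers(2, 6)
        rec_xyz = rng.normal(0, 4, (nr, 3))
        lig_xyz = rng.normal(0, 3, (nl, 3)) + [0, 0, 6]
        while np.min(np.linalg.norm(
                rec_xyz[:, None, :] - lig_xyz[None, :, :], axis=2)) < 1.2:
            lig_xyz = lig_xyz + [0.0, 0.0, 1.0]
        rec = toy_receptor(
            [types[i] for i in rng.integers(0, len(types), nr)],
            rec_xyz, rng.uniform(-0.5, 0.5, nr))
        mol = toy_ligand(
            [types[i] for i in rng.integers(0, len(types), nl)],
            lig_xyz, rng.uniform(-0.5, 0.5, nl))
        got = binding_free_energy(rec, mol, params, tables, directional=True).total
        want = _naive_score(rec, mol, params, tables, directional=True)
        assert got == pytest.approx(want, abs=1e-8)

    def test_rigid_motion_invariance(self, params, tables, receptor_pair, planted):
        from scipy.spatial.transform import Rotation

        mut, _ = receptor_pair
        binder, _ = planted
        ref = binding_free_energy(mut, binder, params, tables)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        shift = np.array([5.0, -3.0, 11.0])
        rec2 = toy_receptor(mut.atom_types, rot.apply(mut.coords) + shift, mut.charges)
        # receptor donor hydrogens must keep their types for E(t)
        mol2 = binder.with_coords(rot.apply(binder.coords) + shift)
        moved = binding_free_energy(rec2, mol2, params, tables, directional=False)
        ref2 = binding_free_energy(mut, binder, params, tables, directional=False)
        for term in ("e_vdw", "e_hbond", "e_elec", "e_tor", "e_dehydration"):
            assert getattr(moved, term) == pytest.approx(getattr(ref2, term), abs=1e-8)

    def test_weight_linearity(self, tables, receptor_pair, planted):
        mut, _ = receptor_pair
        binder, _ = planted
        base = binding_free_energy(mut, binder, default_parameters(), tables)
        doubled = binding_free_energy(
            mut, binder, default_parameters(w_vdw=2 * 0.1485), tables)
        assert doubled.e_vdw == pytest.approx(2 * base.e_vdw, rel=1e-12)
        assert doubled.e_elec == base.e_elec

    def test_all_zero_weights_and_hydration_give_zero(self, receptor_pair, planted):
        mut, _ = receptor_pair
        binder, _ = planted
        params = default_parameters(w_vdw=0.0, w_hbond=0.0, w_elec=0.0, w_tor=0.0)
        hyd = HydrationParamTable(
            {t: (0.0, 1.0, 1.0) for t in default_tables().hydration.types})
        tab = ParameterTables(pair=default_tables().pair, hydration=hyd)
        assert binding_free_energy(mut, binder, params, tab).total == 0.0
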