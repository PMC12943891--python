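"""Generalized-Born, SASA, MM cross terms, frame scoring and decomposition.

Oracles used here are independent of the implementation: numerical
quadrature for the descreening integral, the Born equation for the
single-ion limit, closed-form sphere/cap areas for SASA, brute-force
double loops for pair sums, and a straight-line re-implementation of the
whole per-frame energy.
"""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

from ifacepep.gbsa_scoring import (
    KE_KCAL,
    AtomParams,
    GBSASettings,
    ParamSet,
    aggregate_frames,
    born_radii_obc2,
    debye_kappa,
    gb_polar_energy,
    generic_params,
    intermolecular_mm,
    mmgbsa_frame,
    per_residue_decomposition,
    read_params,
    sasa,
    write_params,
)
from conftest import small_complex

NO_SALT = GBSASettings(salt_molar=0.0)


def quadrature_descreen(r, s, rho):
    """(1/4pi) * integral of |x|^-4 over the scaled sphere (radius s at
    distance r), excluding |x| < rho — by 2D spherical quadrature."""
    def integrand(radius, theta):
        inside = radius**2 - 2 * radius * r * np.cos(theta) + r**2 <= s**2
        return (np.sin(theta) / (2.0 * radius**2)) if inside else 0.0

    val, _ = dblquad(integrand, 0, np.pi, lambda t: rho, lambda t: r + s,
                     epsabs=1e-10, epsrel=1e-8)
    return val


class TestBornRadii:
    def test_isolated_atom_analytic_limit(self):
        ps = ParamSet([AtomParams(0.0, 1.9, 0.1, 1.5, 0.8, 1.5)])
        radii = born_radii_obc2(np.zeros((1, 3)), ps)
        assert radii[0] == pytest.approx(1.41, abs=1e-12)  # rho - offset, psi=0

    @pytest.mark.parametrize("r,s_radius,screen", [
        (4.0, 1.5, 0.8), (2.5, 1.8, 0.9), (6.0, 1.4, 0.72),
    ])
    def test_two_atom_descreening_matches_quadrature(self, r, s_radius, screen):
        settings = GBSASettings()
        ps = ParamSet([
            AtomParams(0.0, 1.9, 0.1, 1.5, 0.0, 1.5),  # probe atom, no backaction
            AtomParams(0.0, 1.9, 0.1, s_radius, screen, 1.5),
        ])
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        radii = born_radii_obc2(coords, ps, settings)
        rho_probe = 1.5 - settings.offset
        scaled = screen * (s_radius - settings.offset)
        descreen = quadrature_descreen(r, scaled, rho_probe)
        psi = rho_probe * descreen
        a, b, g = settings.obc_alpha, settings.obc_beta, settings.obc_gamma
        expected = 1.0 / (1.0 / rho_probe - math.tanh(a * psi - b * psi**2 + g * psi**3) / 1.5)
        assert radii[0] == pytest.approx(expected, rel=0.01)

    def test_effective_radius_never_below_reduced_radius(self, rng):
        for trial in range(30):
            n = int(rng.integers(2, 8))
            coords = rng.uniform(0, 6, size=(n, 3))
            ps = ParamSet([
                AtomParams(0.0, 1.9, 0.1, float(rng.uniform(1.2, 2.2)),
                           float(rng.uniform(0.5, 1.0)), 1.5)
                for _ in range(n)
            ])
            radii = born_radii_obc2(coords, ps)
            assert np.all(radii >= ps.gb_radius - 0.09 - 1e-10)

    def test_radius_below_offset_rejected(self):
        ps = ParamSet([AtomParams(0.0, 1.9, 0.1, 0.05, 0.8, 1.5)])
        with pytest.raises(ValueError):
            born_radii_obc2(np.zeros((1, 3)), ps)


class TestGBPolarEnergy:
    @pytest.mark.parametrize("q", [1.0, -1.0, 2.0, -2.0])
    @pytest.mark.parametrize("radius", [1.0, 2.0, 3.0, 4.0])
    def test_single_ion_born_limit(self, q, radius):
        e = gb_polar_energy(np.zeros((1, 3)), np.array([radius]), np.array([q]), NO_SALT)
        born = -KE_KCAL / 2.0 * (1.0 - 1.0 / 78.5) * q * q / radius
        assert e == pytest.approx(born, rel=1e-3)

    def test_zero_charges_zero_energy(self, rng):
        coords = rng.uniform(0, 5, size=(4, 3))
        e = gb_polar_energy(coords, np.ones(4), np.zeros(4))
        assert e == 0.0

    def test_distant_pair_approaches_screened_coulomb(self):
        r = 200.0
        settings = GBSASettings(salt_molar=0.15)
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        radii = np.array([1.5, 1.5])
        charges = np.array([1.0, 1.0])
        _, pairs = gb_polar_energy(coords, radii, charges, settings, return_pairs=True)
        cross = 2.0 * pairs[0, 1]  # both off-diagonal entries
        kappa = settings.kappa_scale * debye_kappa(0.15)
        expected = -KE_KCAL * (1.0 - math.exp(-kappa * r) / 78.5) / r
        assert cross == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("q2", [1.0, -1.0])
    def test_salt_monotonically_screens_pair_interaction(self, q2):
        # the screened charge-charge interaction (vacuum Coulomb plus the
        # GB reaction-field cross term) must weaken as salt is added
        r = 4.0
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        radii = np.array([1.5, 1.5])
        charges = np.array([1.0, q2])
        magnitudes = []
        for c in (0.0, 0.05, 0.15, 0.5, 1.0):
            _, pairs = gb_polar_energy(
                coords, radii, charges, GBSASettings(salt_molar=c), return_pairs=True
            )
            coulomb = KE_KCAL * charges[0] * charges[1] / r
            magnitudes.append(abs(coulomb + 2.0 * pairs[0, 1]))
        assert all(a >= b - 1e-12 for a, b in zip(magnitudes, magnitudes[1:]))

    def test_negative_salt_rejected(self):
        with pytest.raises(ValueError):
            debye_kappa(-0.1)


class TestSasa:
    def test_single_sphere_analytic(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4, n_points=960)
        assert areas[0] == pytest.approx(4 * math.pi * 3.0**2, rel=0.005)

    def test_fully_buried_atom_is_zero(self):
        coords = np.zeros((2, 3))
        areas = sasa(coords, np.array([1.0, 5.0]), probe=1.4, n_points=960)
        assert areas[0] == 0.0

    def test_two_sphere_overlap_matches_cap_formula(self):
        r1, r2, probe, d = 1.6, 1.4, 1.4, 2.0
        e1, e2 = r1 + probe, r2 + probe
        areas = sasa(np.array([[0.0, 0, 0], [d, 0, 0]]),
                     np.array([r1, r2]), probe=probe, n_points=960)
        cos1 = (d * d + e1 * e1 - e2 * e2) / (2 * d * e1)
        cos2 = (d * d + e2 * e2 - e1 * e1) / (2 * d * e2)
        exp1 = 4 * math.pi * e1**2 - 2 * math.pi * e1**2 * (1 - cos1)
        exp2 = 4 * math.pi * e2**2 - 2 * math.pi * e2**2 * (1 - cos2)
        assert areas[0] == pytest.approx(exp1, rel=0.01)
        assert areas[1] == pytest.approx(exp2, rel=0.01)

    def test_separated_atoms_additive(self, rng):
        radii = rng.uniform(1.2, 2.0, size=5)
        coords = np.arange(5)[:, None] * np.array([50.0, 0.0, 0.0])
        areas = sasa(coords, radii, probe=1.4, n_points=960)
        isolated = 4 * math.pi * (radii + 1.4) ** 2
        np.testing.assert_allclose(areas, isolated, rtol=0.005)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([1.5]), n_points=50)


class TestIntermolecularMM:
    def test_two_unit_charges_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.32, 0, 0]])
        ps = ParamSet([AtomParams(1.0, 1.0, 0.0, 1.5, 0.8, 1.5)] * 2)
        _, e_elec = intermolecular_mm(coords, ps, np.array([0]), np.array([1]))
        assert e_elec == pytest.approx(KE_KCAL / 3.32, rel=1e-12)

    def test_pair_at_lj_minimum(self):
        eps, rmin_half = 0.2, 1.9
        coords = np.array([[0.0, 0, 0], [2 * rmin_half, 0, 0]])
        ps = ParamSet([AtomParams(0.0, rmin_half, eps, 1.5, 0.8, 1.5)] * 2)
        e_vdw, _ = intermolecular_mm(coords, ps, np.array([0]), np.array([1]))
        assert e_vdw == pytest.approx(-eps, rel=1e-12)

    def test_random_split_matches_double_loop(self, rng):
        n = 20
        coords = rng.uniform(0, 12, size=(n, 3))
        ps = ParamSet([
            AtomParams(float(rng.uniform(-1, 1)), float(rng.uniform(1.2, 2.2)),
                       float(rng.uniform(0.01, 0.3)), 1.5, 0.8, 1.5)
            for _ in range(n)
        ])
        rec, lig = np.arange(12), np.arange(12, 20)
        e_vdw, e_elec = intermolecular_mm(coords, ps, rec, lig)
        brute_v = brute_e = 0.0
        for i in rec:
            for j in lig:
                r = float(np.linalg.norm(coords[i] - coords[j]))
                brute_e += KE_KCAL * ps.charges[i] * ps.charges[j] / r
                eps_ij = math.sqrt(ps.epsilon[i] * ps.epsilon[j])
                rmin = ps.rmin_half[i] + ps.rmin_half[j]
                brute_v += eps_ij * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert e_elec == pytest.approx(brute_e, rel=1e-10)
        assert e_vdw == pytest.approx(brute_v, rel=1e-10)

    def test_overlapping_selections_rejected(self, rng):
        coords = rng.uniform(0, 5, size=(4, 3))
        ps = ParamSet([AtomParams(0.1, 1.9, 0.1, 1.5, 0.8, 1.5)] * 4)
        with pytest.raises(ValueError):
            intermolecular_mm(coords, ps, np.array([0, 1]), np.array([1, 2, 3]))


# ---------------------------------------------------------------------------
# straight-line oracle for the full per-frame energy


def plain_hct(r, s, rho):
    if rho >= r + s:
        return 0.0
    L = max(abs(r - s), rho)
    U = r + s
    out = 0.5 * (1 / L - 1 / U + 0.25 * (r - s * s / r) * (1 / U**2 - 1 / L**2)
                 + 0.5 / r * math.log(L / U))
    if rho < s - r:
        out += 1 / rho - 1 / L
    return out


def plain_gb_state(coords, charges, gb_radius, gb_screen, st):
    n = len(coords)
    rho = [gb_radius[i] - st.offset for i in range(n)]
    radii = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i != j:
                r = math.dist(coords[i], coords[j])
                acc += plain_hct(r, gb_screen[j] * rho[j], rho[i])
        psi = rho[i] * acc
        inner = st.obc_alpha * psi - st.obc_beta * psi**2 + st.obc_gamma * psi**3
        radii.append(1.0 / (1.0 / rho[i] - math.tanh(inner) / gb_radius[i]))
    kappa = st.kappa_scale * debye_kappa(st.salt_molar, st.temperature, st.eps_out)
    energy = 0.0
    for i in range(n):
        for j in range(n):
            r2 = math.dist(coords[i], coords[j]) ** 2
            f = math.sqrt(r2 + radii[i] * radii[j] * math.exp(-r2 / (4 * radii[i] * radii[j])))
            energy += (-KE_KCAL / 2.0 * charges[i] * charges[j]
                       * (1.0 / st.eps_in - math.exp(-kappa * f) / st.eps_out) / f)
    return energy


def plain_mmgbsa(coords, ps, rec, lig, st):
    e_vdw = e_elec = 0.0
    for i in rec:
        for j in lig:
            r = math.dist(coords[i], coords[j])
            e_elec += KE_KCAL / st.eps_in * ps.charges[i] * ps.charges[j] / r
            eps_ij = math.sqrt(ps.epsilon[i] * ps.epsilon[j])
            rmin = ps.rmin_half[i] + ps.rmin_half[j]
            e_vdw += eps_ij * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)

    def state(idx):
        return plain_gb_state(
            [coords[i] for i in idx], [ps.charges[i] for i in idx],
            [ps.gb_radius[i] for i in idx], [ps.gb_screen[i] for i in idx], st,
        )

    every = list(rec) + list(lig)
    g_gb = state(every) - state(list(rec)) - state(list(lig))
    # SASA delegated to the package routine (it has its own analytic oracles);
    # a shared quadrature frame matches the binding-difference convention
    from ifacepep.gbsa_scoring import _principal_frame

    frame = _principal_frame(coords[every])
    sasa_all = sasa(coords[every], ps.sasa_radius[every], st.probe, st.sasa_points, frame)
    sasa_r = sasa(coords[list(rec)], ps.sasa_radius[list(rec)], st.probe,
                  st.sasa_points, frame)
    sasa_l = sasa(coords[list(lig)], ps.sasa_radius[list(lig)], st.probe,
                  st.sasa_points, frame)
    g_np = st.gamma_sasa * (sasa_all.sum() - sasa_r.sum() - sasa_l.sum()) + st.beta_offset
    return e_vdw + e_elec + g_gb + g_np


class TestMmgbsaFrame:
    def test_ghost_ligand_binds_with_zero_energy(self):
        asm, coords, params, rec, lig = small_complex(seed=8)
        ghost = ParamSet([
            AtomParams(
                0.0 if i in lig else params.charges[i],
                params.rmin_half[i],
                0.0 if i in lig else params.epsilon[i],
                params.gb_radius[i],
                0.0 if i in lig else params.gb_screen[i],
                params.sasa_radius[i],
            )
            for i in range(len(params))
        ])
        far = coords.copy()
        far[lig] += 8.0  # outside SASA overlap; GB neutrality does the rest
        b = mmgbsa_frame(far, ghost, rec, lig)
        assert b.total == pytest.approx(0.0, abs=1e-9)

    def test_far_ligand_separability(self):
        asm, coords, params, rec, lig = small_complex(seed=3)
        far = coords.copy()
        far[lig] += 250.0
        b = mmgbsa_frame(far, params, rec, lig)
        assert abs(b.total) < 1e-3

    def test_matches_straight_line_reimplementation(self):
        asm, coords, params, rec, lig = small_complex(seed=5)
        st = GBSASettings()
        b = mmgbsa_frame(coords, params, rec, lig, st)
        oracle = plain_mmgbsa(coords, params, rec, lig, st)
        assert b.total == pytest.approx(oracle, abs=1e-8)

    def test_rigid_transform_invariance(self, rng):
        from test_trajectory_analysis import random_rotation

        asm, coords, params, rec, lig = small_complex(seed=2)
        b0 = mmgbsa_frame(coords, params, rec, lig)
        moved = coords @ random_rotation(rng).T + rng.uniform(-30, 30, size=3)
        b1 = mmgbsa_frame(moved, params, rec, lig)
        for attr in ("e_vdw", "e_elec", "g_gb", "g_np", "total"):
            assert getattr(b1, attr) == pytest.approx(getattr(b0, attr), abs=1e-8)

    def test_partition_violations_rejected(self):
        asm, coords, params, rec, lig = small_complex(seed=0)
        with pytest.raises(ValueError):
            mmgbsa_frame(coords, params, rec[:-1], lig)
        with pytest.raises(ValueError):
            mmgbsa_frame(coords, ParamSet([]), rec, lig)


class TestDecomposition:
    def test_residue_totals_sum_to_frame_total_100_frames(self):
        worst = 0.0
        for trial in range(100):
            asm, coords, params, rec, lig = small_complex(seed=trial)
            det = mmgbsa_frame(coords, params, rec, lig, keep_detail=True)
            table = per_residue_decomposition(det, asm, rec, lig)
            worst = max(worst, abs(table["total"].sum() - det.breakdown.total))
        assert worst <= 1e-6

    def test_row_components_sum_to_row_total(self):
        asm, coords, params, rec, lig = small_complex(seed=17)
        det = mmgbsa_frame(coords, params, rec, lig, keep_detail=True)
        table = per_residue_decomposition(det, asm, rec, lig)
        np.testing.assert_allclose(
            table[["vdw", "elec", "polar_solv", "nonpolar_solv"]].sum(axis=1),
            table["total"], atol=1e-9,
        )

    def test_ghost_residue_row_is_zero(self):
        asm, coords, params, rec, lig = small_complex(seed=4)
        # neutralize the second receptor residue entirely and move it far away
        ghost_atoms = np.arange(4, 8)
        p2 = ParamSet([
            AtomParams(
                0.0 if i in ghost_atoms else params.charges[i],
                params.rmin_half[i],
                0.0 if i in ghost_atoms else params.epsilon[i],
                params.gb_radius[i],
                0.0 if i in ghost_atoms else params.gb_screen[i],
                params.sasa_radius[i],
            )
            for i in range(len(params))
        ])
        far = coords.copy()
        far[ghost_atoms] += np.array([500.0, 0.0, 0.0])
        det = mmgbsa_frame(far, p2, rec, lig, keep_detail=True)
        table = per_residue_decomposition(det, asm, rec, lig)
        row = table[table["residue"] == "R.Ala2"].iloc[0]
        for col in ("vdw", "elec", "polar_solv", "nonpolar_solv", "total"):
            assert row[col] == pytest.approx(0.0, abs=1e-9)

    def test_sem_over_frames(self):
        asm, coords, params, rec, lig = small_complex(seed=6)
        frames = [coords, coords + 0.05, coords - 0.05]
        details = [
            mmgbsa_frame(f, params, rec, lig, keep_detail=True) for f in frames
        ]
        table = per_residue_decomposition(details, asm, rec, lig)
        assert np.all(table["sem"].to_numpy() >= 0)


class TestAggregateFrames:
    def test_constant_series_zero_sem(self):
        est = aggregate_frames([-5.0] * 10)
        assert (est.dg_mean, est.dg_sem) == (-5.0, 0.0)

    def test_two_point_closed_form(self):
        est = aggregate_frames([-10.0, -12.0])
        assert est.dg_mean == pytest.approx(-11.0)
        assert est.dg_sem == pytest.approx(1.0)

    def test_last_half_indexing(self):
        series = np.arange(100, dtype=float)
        est = aggregate_frames(series, "last:0.5")
        assert est.n_frames == 50
        assert est.dg_mean == pytest.approx(np.mean(series[50:]))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            aggregate_frames([], None)


class TestParamTables:
    def test_round_trip(self, tmp_path):
        asm, coords, params, rec, lig = small_complex(seed=9)
        path = tmp_path / "params.pqrx"
        write_params(asm, params, path)
        back = read_params(path, asm)
        np.testing.assert_allclose(back.charges, params.charges, atol=1e-6)
        np.testing.assert_allclose(back.gb_radius, params.gb_radius, atol=1e-4)

    def test_mismatched_topology_named_in_error(self, tmp_path):
        asm, coords, params, rec, lig = small_complex(seed=9)
        path = tmp_path / "params.pqrx"
        write_params(asm, params, path)
        asm.chains["P"][0].atoms[0].name = "XX9"
        with pytest.raises(ValueError, match="XX9"):
            read_params(path, asm)

    def test_generic_params_charge_placement(self):
        from ifacepep.structure_io import AssemblyModel, Atom, Residue

        asm = AssemblyModel(model_id=1)
        asm.chains["A"] = [
            Residue("A", 1, "", "LYS", [Atom(1, "NZ", "N", np.zeros(3))]),
            Residue("A", 2, "", "ASP", [
                Atom(2, "OD1", "O", np.array([5.0, 0, 0])),
                Atom(3, "OD2", "O", np.array([6.0, 0, 0])),
            ]),
        ]
        ps = generic_params(asm)
        np.testing.assert_allclose(ps.charges, [1.0, -0.5, -0.5])
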