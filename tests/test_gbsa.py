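"""Energetics: closed-form limits, brute-force oracles, decomposition identities."""

import numpy as np
import pytest

import mdensemble as md
from mdensemble.constants import K_COULOMB
from mdensemble.gbsa import born_radii, cross_pairs, f_gb

from conftest import make_model


def _params(n, charge=0.0, rstar=1.7, eps=0.1, gb=1.5):
    return md.ForceFieldParams(np.full(n, charge), np.full(n, rstar),
                               np.full(n, eps), np.full(n, gb))


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        p = _params(2, charge=1.0)
        e = md.coulomb_energy(coords, p, [[0, 1]])
        assert e == pytest.approx(332.06, abs=1e-9)

    def test_opposite_charges_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.3206, 0, 0]])
        p = md.ForceFieldParams([1.0, -1.0], [1.7, 1.7], [0.1, 0.1], [1.5, 1.5])
        assert md.coulomb_energy(coords, p, [[0, 1]]) == pytest.approx(-100.0,
                                                                      abs=1e-9)

    def test_matches_brute_force(self, rng):
        coords = rng.random((4, 3)) * 8
        q = rng.standard_normal(4)
        p = md.ForceFieldParams(q, np.full(4, 1.7), np.full(4, 0.1), np.full(4, 1.5))
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        expected = sum(K_COULOMB * q[i] * q[j] / np.linalg.norm(coords[i] - coords[j])
                       for i, j in pairs)
        assert md.coulomb_energy(coords, p, pairs) == pytest.approx(expected,
                                                                    abs=1e-10)

    def test_coincident_atoms_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            md.coulomb_energy(coords, _params(2, charge=1.0), [[0, 1]])


class TestLennardJones:
    def test_minimum_at_rstar_sum(self):
        p = md.ForceFieldParams([0, 0], [1.6, 1.9], [0.2, 0.05], [1.5, 1.5])
        coords = np.array([[0.0, 0, 0], [3.5, 0, 0]])  # r = R*_i + R*_j
        e = md.lj_energy(coords, p, [[0, 1]])
        assert e == pytest.approx(-np.sqrt(0.2 * 0.05), abs=1e-12)

    def test_decay_at_ten_rmin(self):
        p = _params(2, eps=0.3)
        coords = np.array([[0.0, 0, 0], [34.0, 0, 0]])
        assert abs(md.lj_energy(coords, p, [[0, 1]])) < 1e-4 * 0.3

    def test_three_atom_brute_force(self, rng):
        coords = rng.random((3, 3)) * 6 + np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        rstar = np.array([1.5, 1.7, 1.9])
        eps = np.array([0.1, 0.2, 0.05])
        p = md.ForceFieldParams(np.zeros(3), rstar, eps, np.full(3, 1.5))
        pairs = [(0, 1), (0, 2), (1, 2)]
        expected = 0.0
        for i, j in pairs:
            r = np.linalg.norm(coords[i] - coords[j])
            rmin = rstar[i] + rstar[j]
            e = np.sqrt(eps[i] * eps[j])
            expected += e * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert md.lj_energy(coords, p, pairs) == pytest.approx(expected, abs=1e-10)


def mc_descreen_integral(xi, rho_i, xj, rho_j, n=400_000, seed=0):
    """Monte-Carlo oracle for the HCT descreening term: (1/4pi) times the
    integral of |x - xi|^-4 over sphere j excluding atom i's own sphere."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    radii = rho_j * rng.random(n) ** (1 / 3)
    pts = xj + pts * radii[:, None]
    d = np.linalg.norm(pts - xi, axis=1)
    inside_own = d < rho_i
    integrand = np.where(inside_own, 0.0, 1.0 / d ** 4)
    vol = 4 / 3 * np.pi * rho_j ** 3
    return vol * integrand.mean() / (4 * np.pi)


class TestGeneralizedBorn:
    def test_single_ion_born_self_energy(self):
        q, r = 2.0, 1.7
        p = md.ForceFieldParams([q], [1.7], [0.1], [r])
        e = md.gb_energy(np.zeros((1, 3)), p, solvent_dielectric=80.0,
                         solute_dielectric=1.0)
        expected = -0.5 * (1 - 1 / 80.0) * K_COULOMB * q * q / r
        assert e == pytest.approx(expected, rel=1e-3)

    def test_two_distant_ions_additive(self):
        p = md.ForceFieldParams([1.0, 1.0], [1.7, 1.7], [0.1, 0.1], [2.0, 1.4])
        # the screened cross term decays only as 1/r, so "infinite" must be big
        coords = np.array([[0.0, 0, 0], [1e9, 0, 0]])
        e = md.gb_energy(coords, p)
        singles = sum(
            md.gb_energy(np.zeros((1, 3)), p.subset([i])) for i in range(2))
        assert e == pytest.approx(singles, rel=1e-6)

    def test_two_atom_f_gb_arithmetic_oracle(self):
        # independent literal evaluation of the pair energy at 3 Å
        r, r1, r2, q1, q2 = 3.0, 1.5, 1.8, 0.4, -0.7
        p = md.ForceFieldParams([q1, q2], [1.7, 1.7], [0.1, 0.1], [r1, r2])
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        reff = np.array([r1, r2])  # explicit radii: isolate the f_GB form
        e = md.gb_energy(coords, p, 78.5, 1.0, radii=reff)
        tau = 1.0 - 1.0 / 78.5
        f12 = np.sqrt(r * r + r1 * r2 * np.exp(-(r * r) / (4 * r1 * r2)))
        expected = -0.5 * tau * K_COULOMB * (
            q1 * q1 / r1 + q2 * q2 / r2 + 2 * q1 * q2 / f12)
        assert e == pytest.approx(expected, abs=1e-8)

    def test_screened_coulomb_limit_at_50A(self):
        q1, q2 = 0.8, -0.5
        p = md.ForceFieldParams([q1, q2], [1.7, 1.7], [0.1, 0.1], [1.5, 1.5])
        r = 50.0
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        e_pair = md.gb_energy(coords, p, 80.0, 1.0) - \
            md.gb_energy(coords[:1], p.subset([0]), 80.0, 1.0) - \
            md.gb_energy(coords[1:], p.subset([1]), 80.0, 1.0)
        expected = -(1 - 1 / 80.0) * K_COULOMB * q1 * q2 / r
        assert e_pair == pytest.approx(expected, rel=0.01)

    def test_born_radii_isolated_equals_intrinsic(self):
        p = _params(1, gb=2.2)
        assert born_radii(np.zeros((1, 3)), p)[0] == pytest.approx(2.2)

    def test_born_radii_match_monte_carlo_descreening(self):
        rho = np.array([1.5, 1.2])
        coords = np.array([[0.0, 0, 0], [3.1, 0, 0]])
        p = md.ForceFieldParams([0, 0], [1.7, 1.7], [0.1, 0.1], rho)
        reff = born_radii(coords, p)
        for i, j in ((0, 1), (1, 0)):
            integral = mc_descreen_integral(coords[i], rho[i], coords[j], rho[j])
            expected = 1.0 / (1.0 / rho[i] - integral)
            assert reff[i] == pytest.approx(expected, rel=0.01)

    def test_descreening_grows_radii(self):
        # a neighbour displaces solvent: the effective radius must exceed the
        # intrinsic one, and more so when the neighbour is closer
        p = _params(2, gb=1.5)
        r_far = born_radii(np.array([[0.0, 0, 0], [8.0, 0, 0]]), p)[0]
        r_near = born_radii(np.array([[0.0, 0, 0], [3.2, 0, 0]]), p)[0]
        assert 1.5 < r_far < r_near


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        area, total = md.sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4,
                              n_points=960)
        assert total == pytest.approx(4 * np.pi * 3.0 ** 2, rel=1e-6)
        assert total == pytest.approx(113.10, abs=0.02)

    def test_distant_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.6, 2.0])
        _, total = md.sasa(coords, radii, 1.4, 960)
        singles = sum(md.sasa(coords[i:i + 1], radii[i:i + 1], 1.4, 960)[1]
                      for i in range(2))
        assert total == pytest.approx(singles, rel=1e-9)

    def test_fused_dimer_matches_analytic_caps(self):
        # two intersecting spheres: accessible area from spherical-cap formula
        r1, r2, d = 3.0, 2.6, 3.5
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        _, total = md.sasa(coords, np.array([r1 - 1.4, r2 - 1.4]), 1.4, 20_000)
        c1 = (d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d)
        h1 = r1 - c1
        h2 = r2 - (d - c1)
        analytic = 4 * np.pi * r1 ** 2 - 2 * np.pi * r1 * h1 \
            + 4 * np.pi * r2 ** 2 - 2 * np.pi * r2 * h2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_nonpolar_linear_form(self):
        assert md.nonpolar_energy(1000.0, 0.0072, 0.0) == pytest.approx(7.2)
        assert md.nonpolar_energy(0.0, 0.0072, 0.25) == pytest.approx(0.25)
        assert md.nonpolar_energy(-1500.0, 0.0072, 0.0) == pytest.approx(-10.8)


class TestBindingEnergy:
    def _toy(self, n_frames=4, separation=4.0, seed=0):
        traj, q, rs, eps, gb, ri, li = md.generate_binding_toy(
            n_frames, seed=seed, separation=separation)
        params = md.ForceFieldParams(q, rs, eps, gb)
        rec = traj.topology.select("chain R")
        lig = traj.topology.select("chain L")
        return traj, params, rec, lig

    def test_noninteracting_limit(self):
        traj, q, rs, eps, gb, ri, li = md.generate_binding_toy(
            3, seed=1, separation=500.0, jitter=0.0)
        params = md.ForceFieldParams(np.zeros_like(q), rs, eps, gb)
        rec = traj.topology.select("chain R")
        lig = traj.topology.select("chain L")
        dec = md.binding_energy(traj, rec, lig, params, n_points=240)
        assert abs(dec.means["dG_binding"]) < 1e-6

    def test_per_frame_identities(self):
        traj, params, rec, lig = self._toy()
        dec = md.binding_energy(traj, rec, lig, params, n_points=240)
        pf = dec.per_frame
        assert np.abs(pf["dE_gas"] - (pf["dE_vdW"] + pf["dE_ele"])).max() < 1e-9
        assert np.abs(pf["dG_solvation"] - (pf["dG_GB"] + pf["dG_nonpolar"])).max() < 1e-9
        assert np.abs(pf["dG_binding"] - (pf["dE_gas"] + pf["dG_solvation"])).max() < 1e-9

    def test_two_particle_hand_calculation(self):
        # one receptor atom + one ligand atom, fixed geometry: every term has
        # a literal closed form (Coulomb + LJ + Born pair + gamma*dSASA)
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        model = make_model(coords, chains=["R", "L"], resids=[1, 2])
        traj = md.Trajectory(model, coords[None])
        q = np.array([0.5, -0.5])
        rstar = np.array([1.7, 1.7])
        eps = np.array([0.1, 0.1])
        gb = np.array([1.5, 1.5])
        params = md.ForceFieldParams(q, rstar, eps, gb)
        rec, lig = model.select("chain R"), model.select("chain L")
        n_pts = 4000
        dec = md.binding_energy(traj, rec, lig, params, n_points=n_pts)
        r = 4.0
        e_ele = K_COULOMB * q[0] * q[1] / r
        x6 = ((rstar[0] + rstar[1]) / r) ** 6
        e_vdw = np.sqrt(eps[0] * eps[1]) * (x6 * x6 - 2 * x6)
        assert dec.means["dE_ele"] == pytest.approx(e_ele, abs=1e-9)
        assert dec.means["dE_vdW"] == pytest.approx(e_vdw, abs=1e-9)
        # polar: complex GB minus the two isolated self energies
        reff = born_radii(coords, params)
        tau = 1.0 / 1.0 - 1.0 / 78.5
        f12 = f_gb(np.array([r]), reff[0], reff[1])[0]
        e_gb_c = -0.5 * tau * K_COULOMB * (q[0] ** 2 / reff[0] +
                                           q[1] ** 2 / reff[1] +
                                           2 * q[0] * q[1] / f12)
        e_gb_sep = -0.5 * tau * K_COULOMB * (q[0] ** 2 / gb[0] + q[1] ** 2 / gb[1])
        assert dec.means["dG_GB"] == pytest.approx(e_gb_c - e_gb_sep, abs=1e-8)
        # nonpolar: spheres 4 Å apart with radius 1.5+1.4 overlap slightly
        _, s_c = md.sasa(coords, gb, 1.4, n_pts)
        s_sep = sum(md.sasa(coords[i:i+1], gb[i:i+1], 1.4, n_pts)[1]
                    for i in range(2))
        assert dec.means["dG_nonpolar"] == pytest.approx(
            0.0072 * (s_c - s_sep), abs=1e-9)

    def test_receptor_ligand_swap_invariant(self):
        traj, params, rec, lig = self._toy()
        d1 = md.binding_energy(traj, rec, lig, params, n_points=240)
        d2 = md.binding_energy(traj, lig, rec, params, n_points=240)
        assert d1.means["dG_binding"] == pytest.approx(d2.means["dG_binding"],
                                                       abs=1e-9)

    def test_rigid_transform_invariance(self):
        from scipy.spatial.transform import Rotation
        traj, params, rec, lig = self._toy(n_frames=2)
        rot = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
        moved = md.Trajectory(traj.topology, traj.coords @ rot.T + 7.0)
        d1 = md.binding_energy(traj, rec, lig, params, n_points=960)
        d2 = md.binding_energy(moved, rec, lig, params, n_points=960)
        # gas + polar terms are exactly invariant; the nonpolar term carries
        # the orientation-dependent quadrature error of the sphere point set
        assert d1.means["dG_binding_no_nonpolar"] == pytest.approx(
            d2.means["dG_binding_no_nonpolar"], abs=1e-6)
        assert d1.means["dG_nonpolar"] == pytest.approx(
            d2.means["dG_nonpolar"], abs=0.03)

    def test_overlapping_selections_rejected(self):
        traj, params, rec, lig = self._toy()
        bad = md.AtomSelection(np.arange(0, 7), "bad", "bad")
        with pytest.raises(md.errors.SelectionError, match="overlap"):
            md.binding_energy(traj, rec, bad, params)


class TestAggregation:
    def test_identical_decompositions_zero_difference(self):
        traj, q, rs, eps, gb, ri, li = md.generate_binding_toy(3, seed=4)
        params = md.ForceFieldParams(q, rs, eps, gb)
        rec = traj.topology.select("chain R")
        lig = traj.topology.select("chain L")
        d = md.binding_energy(traj, rec, lig, params, n_points=240)
        diff = md.aggregate_and_compare(d, d)
        assert np.allclose(diff["ddG (A - B)"].to_numpy(), 0.0)

    def test_published_table_totals(self):
        # the printed per-term energies reproduce the printed totals exactly
        assert md.total_from_terms(-1840.20, -191.96, 1945.76) == pytest.approx(
            -86.40, abs=1e-9)
        ddg = -112.98 - (-86.40)
        assert ddg == pytest.approx(-26.58, abs=1e-9)

    def test_parameter_table_round_trip(self, tmp_path):
        p = md.ForceFieldParams([0.3, -0.3], [1.6, 1.8], [0.1, 0.2], [1.4, 1.9])
        path = tmp_path / "params.csv"
        path.write_text(p.to_table())
        back = md.ForceFieldParams.from_table(path)
        assert np.allclose(back.charge, p.charge)
        assert np.allclose(back.gb_radius, p.gb_radius)
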