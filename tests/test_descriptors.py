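"""Energy, solvation, SASA, hydrogen-bond and stability descriptors."""

import math

import numpy as np
import pytest

import fdgamd as fg
from fdgamd.descriptors import hct_effective_radii, mmgbsa_frame
from fdgamd.model_io import (
    COULOMB_CONSTANT,
    SOLVENT_DIELECTRIC,
    DomainError,
    SingularityError,
)
from fdgamd.trajectory_ops import LigandCopyTrajectory
from conftest import brute_force_nonbonded


def _pair_system(r, q_rec=0.0, q_lig=0.0, eps=0.2, rmin_half=1.8,
                 rec_element="C", lig_element="C"):
    atoms = [
        fg.AtomRecord(serial=1, name="A1", element=rec_element,
                      residue_name="GLY", residue_id=1, charge=q_rec,
                      lj_epsilon=eps, lj_rmin_half=rmin_half),
        fg.AtomRecord(serial=2, name="B1", element=lig_element,
                      residue_name="LIG", residue_id=2, chain_or_copy="1",
                      charge=q_lig, lj_epsilon=eps, lj_rmin_half=rmin_half),
    ]
    topo = fg.Topology(atoms=atoms, molecule_kinds=["receptor", "ligand"],
                       n_ligand_copies=1)
    frame = fg.Frame(time_ns=0.0,
                     coordinates=np.array([[0.0, 0, 0], [r, 0.0, 0.0]]))
    return topo, frame


class TestNonbondedEnergy:
    def test_zero_charges_give_zero_electrostatics(self):
        topo, frame = _pair_system(3.0)
        rep = fg.nonbonded_inter_energy(frame, topo)
        assert rep.e_elec == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        eps, rmin_half = 0.21, 1.7
        topo, frame = _pair_system(2 * rmin_half, eps=eps,
                                   rmin_half=rmin_half)
        rep = fg.nonbonded_inter_energy(frame, topo)
        assert rep.e_vdw == pytest.approx(-eps, rel=1e-12)

    def test_matches_brute_force_on_random_system(self, energy_system):
        topo, frame = energy_system
        rep = fg.nonbonded_inter_energy(frame, topo)
        e_vdw, e_elec = brute_force_nonbonded(
            frame, topo, topo.indices_of_kind("receptor"),
            topo.indices_of_kind("ligand"))
        assert rep.e_vdw == pytest.approx(e_vdw, abs=1e-9)
        assert rep.e_elec == pytest.approx(e_elec, abs=1e-9)

    def test_decomposition_closure(self, energy_system):
        topo, frame = energy_system
        rep = fg.nonbonded_inter_energy(frame, topo)
        assert rep.e_inter == rep.e_vdw + rep.e_elec

    def test_overlapping_atoms_singularity_names_pair(self):
        topo, frame = _pair_system(1e-9)
        with pytest.raises(SingularityError, match="serial"):
            fg.nonbonded_inter_energy(frame, topo)


class TestGeneralizedBorn:
    def test_zero_charges_give_exact_zero(self):
        coords = np.random.default_rng(0).uniform(-3, 3, (5, 3))
        assert fg.gb_polar_energy(coords, np.zeros(5), np.full(5, 1.5)) == 0.0

    def test_single_ion_matches_born_formula(self):
        q, rho = 1.0, 1.5
        expected = -0.5 * (1 - 1 / SOLVENT_DIELECTRIC) * COULOMB_CONSTANT \
            * q * q / rho
        got = fg.gb_polar_energy(np.zeros((1, 3)), np.array([q]),
                                 np.array([rho]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_lone_atom_effective_radius_is_intrinsic(self):
        rho = np.array([1.61])
        np.testing.assert_allclose(
            hct_effective_radii(np.zeros((1, 3)), rho), rho)

    def test_distant_pair_is_additive(self):
        # the screened cross term decays as 1/r, so 0.1 % additivity needs
        # a genuinely large separation
        coords = np.array([[0.0, 0, 0], [5000.0, 0, 0]])
        q = np.array([0.5, -0.8])
        rho = np.array([1.4, 1.7])
        together = fg.gb_polar_energy(coords, q, rho)
        separate = sum(
            fg.gb_polar_energy(np.zeros((1, 3)), q[i:i + 1], rho[i:i + 1])
            for i in range(2))
        assert together == pytest.approx(separate, rel=1e-3)

    def test_nonpositive_for_any_charge_set(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(2, 8)
            coords = rng.uniform(-4, 4, (n, 3))
            q = rng.uniform(-1, 1, n)
            rho = rng.uniform(1.0, 2.0, n)
            assert fg.gb_polar_energy(coords, q, rho) <= 0.0

    def test_quadratic_charge_scaling(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-4, 4, (6, 3))
        q = rng.uniform(-0.5, 0.5, 6)
        rho = np.full(6, 1.5)
        base = fg.gb_polar_energy(coords, q, rho)
        scaled = fg.gb_polar_energy(coords, 2.0 * q, rho)
        assert scaled == pytest.approx(4.0 * base, rel=1e-9)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DomainError):
            fg.gb_polar_energy(np.zeros((1, 3)), np.array([1.0]),
                               np.array([0.0]))


class TestSASA:
    def test_isolated_atom_matches_sphere_area_within_2_percent(self):
        r = 1.7
        area = fg.sasa(np.zeros((1, 3)), np.array([r]), n_points=960).sum()
        exact = 4 * math.pi * (r + 1.4) ** 2
        assert abs(area - exact) / exact < 0.02

    def test_distant_atoms_additive(self):
        radii = np.array([1.7, 1.5])
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        total = fg.sasa(coords, radii, n_points=960).sum()
        parts = sum(fg.sasa(np.zeros((1, 3)), radii[i:i + 1],
                            n_points=960).sum() for i in range(2))
        assert total == pytest.approx(parts, abs=1e-6)

    def test_caged_atom_nearly_buried(self):
        # octahedral cage of large spheres around a small central atom
        cage = 2.4 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                               [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.array([1.2] + [2.4] * 6)
        per_atom = fg.sasa(coords, radii, n_points=960)
        free = fg.sasa(np.zeros((1, 3)), radii[:1], n_points=960).sum()
        assert per_atom[0] < 0.01 * free

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-4, 4, (8, 3))
        radii = rng.uniform(1.2, 1.9, 8)
        a = fg.sasa(coords, radii)
        b = fg.sasa(coords, radii)
        np.testing.assert_array_equal(a, b)

    def test_cross_check_against_independent_implementation(self):
        import biotite.structure as struc
        rng = np.random.default_rng(7)
        n = 12
        coords = rng.uniform(-5, 5, (n, 3)).astype(np.float32)
        radii = rng.uniform(1.3, 1.9, n)
        arr = struc.AtomArray(n)
        arr.coord = coords
        arr.set_annotation("element", np.array(["C"] * n))
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                         point_number=1000)
        mine = fg.sasa(coords.astype(float), radii, n_points=1000)
        np.testing.assert_allclose(mine.sum(), ref.sum(), rtol=0.03)


class TestNonpolarTerm:
    @pytest.mark.parametrize("area, expected", [(0.0, 0.0), (1000.0, 7.2)])
    def test_linear_in_area(self, area, expected):
        assert fg.sa_nonpolar_energy(area) == pytest.approx(expected)

    def test_doubling_area_doubles_energy(self):
        assert fg.sa_nonpolar_energy(500.0) * 2 == pytest.approx(
            fg.sa_nonpolar_energy(1000.0))

    def test_negative_area_rejected(self):
        with pytest.raises(DomainError):
            fg.sa_nonpolar_energy(-1.0)


class TestMMGBSA:
    def test_infinite_separation_limit_vanishes(self):
        topo, _ = _pair_system(3.0, q_rec=0.3, q_lig=-0.3,
                               rec_element="O", lig_element="N")
        frame = fg.Frame(time_ns=0.0,
                         coordinates=np.array([[0.0, 0, 0], [500.0, 0, 0]]))
        rep = mmgbsa_frame(frame, topo, sasa_points=960)
        assert abs(rep.dg_bind_mmgbsa) < 1e-3

    def test_zero_charges_reduce_to_vdw_plus_sa(self):
        topo, frame = _pair_system(3.4, rec_element="O", lig_element="N")
        rep = mmgbsa_frame(frame, topo, sasa_points=960)
        assert rep.e_elec == 0.0
        assert rep.dg_gb == pytest.approx(0.0, abs=1e-12)
        assert rep.dg_bind_mmgbsa == pytest.approx(rep.e_vdw + rep.dg_sa)

    def test_opposite_charges_at_contact_bind(self):
        topo, frame = _pair_system(3.2, q_rec=0.5, q_lig=-0.5,
                                   rec_element="O", lig_element="N")
        rep = mmgbsa_frame(frame, topo, sasa_points=960)
        assert rep.dg_bind_mmgbsa < 0.0

    def test_intramolecular_term_is_structurally_zero(self):
        topo, frame = _pair_system(3.0)
        rep = mmgbsa_frame(frame, topo)
        assert rep.de_intra == 0.0
        assert rep.dg_bind_mmgbsa == pytest.approx(
            rep.e_inter + rep.dg_gb + rep.dg_sa)


class TestStabilityFilter:
    def test_constant_series_kept(self):
        times = np.arange(0.0, 60.0, 2.0)
        rep = fg.stability_filter(times, np.full(len(times), -20.0))
        assert rep.keep and rep.evaluable

    def test_shifted_block_discarded_against_recomputation(self):
        import pandas as pd
        times = np.arange(0.0, 60.0, 2.0)
        series = np.where((times >= 20) & (times < 30), -5.0, -20.0)
        series = series + np.linspace(0, 0.1, len(times))   # slight drift
        rep = fg.stability_filter(times, series)
        # independent recomputation of the block statistics
        frame = pd.DataFrame({"block": (times // 10).astype(int),
                              "dg": series})
        means = frame.groupby("block").dg.mean()
        assert rep.keep is False
        assert np.any(np.abs(means - means.mean()) > 2.0 * means.std(ddof=1))
        np.testing.assert_allclose(np.sort(rep.block_means),
                                   np.sort(means.values))

    def test_exactly_at_scale_boundary_kept(self):
        # block means (-10, -10, -13): max deviation 2, sd sqrt(3); a scale
        # of 2/sqrt(3) puts the worst block exactly at the boundary, which
        # keeps (strictly-exceeding discards)
        times = np.arange(0.0, 30.0, 2.0)
        series = np.where(times < 20, -10.0, -13.0)
        boundary_scale = 2.0 / math.sqrt(3.0)
        assert fg.stability_filter(times, series,
                                   scale=boundary_scale).keep is True
        assert fg.stability_filter(times, series,
                                   scale=0.99 * boundary_scale).keep is False

    def test_short_series_flagged_not_evaluable(self):
        rep = fg.stability_filter(np.array([0.0, 2.0]),
                                  np.array([-10.0, -11.0]))
        assert rep.keep and not rep.evaluable


def _hbond_trajectory(n_frames=10, satisfy=None, distance=2.9, angle=180.0):
    """Receptor O acceptor at origin; ligand N-H donor aimed at it."""
    satisfy = satisfy if satisfy is not None else [True] * n_frames
    atoms = [
        fg.AtomRecord(serial=1, name="O", element="O", residue_name="SER",
                      residue_id=1),
        fg.AtomRecord(serial=2, name="N1", element="N", residue_name="LIG",
                      residue_id=2, chain_or_copy="1",
                      is_repulsive_center=True),
        fg.AtomRecord(serial=3, name="H1", element="H", residue_name="LIG",
                      residue_id=2, chain_or_copy="1"),
    ]
    topo = fg.Topology(atoms=atoms,
                       molecule_kinds=["receptor", "ligand", "ligand"],
                       n_ligand_copies=1)
    frames = []
    theta = math.radians(180.0 - angle)
    for t, ok in enumerate(satisfy):
        d = distance if ok else 6.0
        n_pos = np.array([0.0, 0.0, d])
        h_pos = n_pos + np.array([math.sin(theta), 0.0, -math.cos(theta)])
        frames.append(fg.Frame(time_ns=float(t * 2),
                               coordinates=np.vstack([[0, 0, 0], n_pos,
                                                      h_pos])))
    return LigandCopyTrajectory(copy_id=1,
                                trajectory=fg.Trajectory(topology=topo,
                                                         frames=frames))


class TestHydrogenBonds:
    def test_ideal_linear_bond_fully_occupied_and_retained(self):
        traj = _hbond_trajectory()
        rep = fg.hydrogen_bonds(traj, window_ns=20.0)
        assert rep.pairs and rep.pairs[0][3] == 1.0
        assert rep.n_retained == 1

    def test_forty_percent_occupancy_not_retained(self):
        satisfy = [True] * 4 + [False] * 6
        rep = fg.hydrogen_bonds(_hbond_trajectory(satisfy=satisfy))
        assert rep.pairs[0][3] == pytest.approx(0.4)
        assert rep.n_retained == 0

    def test_bent_geometry_rejected(self):
        rep = fg.hydrogen_bonds(_hbond_trajectory(angle=100.0))
        assert rep.n_retained == 0

    def test_long_distance_rejected(self):
        rep = fg.hydrogen_bonds(_hbond_trajectory(distance=3.5))
        assert all(p[3] == 0.0 for p in rep.pairs)

    def test_matches_brute_force_triple_scan(self):
        rng = np.random.default_rng(2)
        n_rec, n_lig = 12, 6
        atoms, kinds = [], []
        for i in range(n_rec):
            atoms.append(fg.AtomRecord(
                serial=i + 1, name=f"R{i}", element=["O", "N", "C"][i % 3],
                residue_name="GLY", residue_id=i + 1))
            kinds.append("receptor")
        for j in range(n_lig):
            atoms.append(fg.AtomRecord(
                serial=n_rec + j + 1, name=f"L{j}",
                element=["N", "H", "O", "H", "C", "H"][j],
                residue_name="LIG", residue_id=100, chain_or_copy="1",
                is_repulsive_center=(j == 0)))
            kinds.append("ligand")
        topo = fg.Topology(atoms=atoms, molecule_kinds=kinds,
                           n_ligand_copies=1)
        frames = []
        for t in range(5):
            rec = rng.uniform(-3, 3, (n_rec, 3))
            base = rng.uniform(-3, 3, 3)
            lig = base + rng.uniform(-1.1, 1.1, (n_lig, 3))
            frames.append(fg.Frame(time_ns=float(t * 2),
                                   coordinates=np.vstack([rec, lig])))
        traj = LigandCopyTrajectory(copy_id=1,
                                    trajectory=fg.Trajectory(topology=topo,
                                                             frames=frames))
        rep = fg.hydrogen_bonds(traj, window_ns=100.0)
        got = {(d, h, a): o for d, h, a, o in rep.pairs}

        # oracle: exhaustive all-triples geometric scan (the donor-H
        # assignment convention -- first polar heavy atom within 1.25 Å of
        # each hydrogen -- is shared; the per-frame geometry is independent)
        coords0 = frames[0].coordinates
        polar = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
        hydros = [i for i, a in enumerate(atoms) if a.element == "H"]
        dh_pairs = []
        for h in hydros:
            close = [d for d in polar
                     if np.linalg.norm(coords0[h] - coords0[d]) <= 1.25]
            if close:
                dh_pairs.append((close[0], h))
        expected = {}
        for d, h in dh_pairs:
            for a in polar:
                    if a == d or kinds[a] == kinds[d]:
                        continue
                    count = 0
                    for fr in frames:
                        c = fr.coordinates
                        if np.linalg.norm(c[a] - c[d]) > 3.0:
                            continue
                        v1 = c[d] - c[h]
                        v2 = c[a] - c[h]
                        cosang = v1 @ v2 / (np.linalg.norm(v1)
                                            * np.linalg.norm(v2))
                        if math.degrees(math.acos(np.clip(cosang, -1, 1))) \
                                >= 135.0:
                            count += 1
                    expected[(d, h, a)] = count / len(frames)
        assert got == expected


class TestPercentExposed:
    def test_unburied_ligand_near_full_exposure(self):
        topo, frame = _pair_system(25.0, rec_element="C", lig_element="N")
        rep = fg.percent_exposed(frame, topo)
        assert rep.percent_exposed == pytest.approx(100.0, abs=0.5)

    def test_caged_ligand_mostly_buried(self):
        cage = 2.6 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                               [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        atoms = [fg.AtomRecord(serial=i + 1, name="S", element="S",
                               residue_name="GLY", residue_id=i + 1)
                 for i in range(6)]
        atoms.append(fg.AtomRecord(serial=7, name="N1", element="N",
                                   residue_name="LIG", residue_id=10,
                                   chain_or_copy="1",
                                   is_repulsive_center=True))
        topo = fg.Topology(atoms=atoms,
                           molecule_kinds=["receptor"] * 6 + ["ligand"],
                           n_ligand_copies=1)
        frame = fg.Frame(time_ns=0.0,
                         coordinates=np.vstack([cage, [0.0, 0.0, 0.0]]))
        rep = fg.percent_exposed(frame, topo, n_points=960)
        assert rep.percent_exposed < 5.0

    def test_rigid_motion_invariance(self, energy_system):
        topo, frame = energy_system
        a = fg.percent_exposed(frame, topo).percent_exposed
        moved = fg.Frame(time_ns=0.0,
                         coordinates=frame.coordinates + [50.0, -20.0, 7.0])
        b = fg.percent_exposed(moved, topo).percent_exposed
        assert a == pytest.approx(b, abs=1e-6)
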