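"""System preparation: axes, box tiling, repulsive term, GaMD schedule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fdgamd as fg
from fdgamd.descriptors import lj_pair_energy
from fdgamd.model_io import (
    DegeneracyError,
    PlacementError,
    SelectionError,
    UnsupportedElementError,
    ValidationError,
)
from fdgamd.system_prep import tiling_counts


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestEquilSchedule:
    @pytest.mark.parametrize("n_atoms, expected", [
        (1, (4, 8, 8, 20)),
        (25000, (100000, 200000, 200000, 500000)),
    ])
    def test_step_counts(self, n_atoms, expected):
        s = fg.gamd_equilibration_schedule(n_atoms)
        assert (s.ntave, s.ntcmdprep, s.ntebprep, s.ntcmd) == expected

    @given(st.integers(min_value=1, max_value=10**7))
    def test_ratios_hold_for_any_system_size(self, n):
        s = fg.gamd_equilibration_schedule(n)
        assert s.ntcmd == 5 * s.ntave
        assert s.ntcmdprep == s.ntebprep == 2 * s.ntave
        assert s.ntave == 4 * n

    def test_rejects_empty_system(self):
        with pytest.raises(ValidationError):
            fg.gamd_equilibration_schedule(0)


class TestPrincipalAxes:
    def test_rod_on_x_axis_recovered(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 0.1, 0]])
        axes = fg.principal_axes(coords, np.ones(3))
        assert abs(abs(axes[0] @ [1, 0, 0]) - 1) < 1e-6

    def test_axes_orthonormal_right_handed(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((30, 3)) * [5, 2, 1]
        axes = fg.principal_axes(coords, rng.uniform(1, 12, 30))
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(axes) == pytest.approx(1.0)

    def test_rotated_rod_recovered_against_eig_oracle(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((60, 3)) * [8, 1, 0.5]
        masses = rng.uniform(1, 16, 60)
        rot = _random_rotation(rng)
        coords = base @ rot.T
        axes = fg.principal_axes(coords, masses)
        # oracle: covariance built by an explicit double loop
        com = (coords * masses[:, None]).sum(0) / masses.sum()
        cov = np.zeros((3, 3))
        for x, m in zip(coords, masses):
            d = x - com
            for a in range(3):
                for b in range(3):
                    cov[a, b] += m * d[a] * d[b]
        cov /= masses.sum()
        evals, evecs = np.linalg.eigh(cov)
        oracle_first = evecs[:, np.argmax(evals)]
        assert min(np.linalg.norm(axes[0] - oracle_first),
                   np.linalg.norm(axes[0] + oracle_first)) < 1e-6

    def test_collinear_points_degenerate(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegeneracyError):
            fg.principal_axes(coords, np.ones(3))


class TestAlignment:
    def _cloud(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        coords = rng.standard_normal((n, 3)) * [6, 2, 1] + [3, -5, 2]
        atoms = [fg.AtomRecord(serial=i + 1, name="CA", element="C",
                               residue_name="GLY", residue_id=i + 1)
                 for i in range(n)]
        topo = fg.Topology(atoms=atoms, molecule_kinds=["receptor"] * n)
        return fg.Frame(time_ns=0.0, coordinates=coords), topo

    def test_rigid_motion_preserves_distances(self):
        frame, topo = self._cloud()
        rotated, _ = fg.align_to_principal_axes(frame, topo)
        before = np.linalg.norm(frame.coordinates[:, None]
                                - frame.coordinates[None], axis=2)
        after = np.linalg.norm(rotated.coordinates[:, None]
                               - rotated.coordinates[None], axis=2)
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_already_aligned_rotation_is_signed_identity(self):
        frame, topo = self._cloud(seed=5)
        once, _ = fg.align_to_principal_axes(frame, topo)
        twice, rot = fg.align_to_principal_axes(once, topo)
        np.testing.assert_allclose(np.abs(rot), np.eye(3), atol=1e-9)

    def test_alignment_never_grows_bounding_box(self):
        # elongated cloud: axis alignment minimises the box over rotations
        frame, topo = self._cloud(seed=9)
        aligned, _ = fg.align_to_principal_axes(frame, topo)
        vol_aligned = np.prod(aligned.coordinates.max(0)
                              - aligned.coordinates.min(0))
        rng = np.random.default_rng(1)
        for _ in range(100):
            rot = _random_rotation(rng)
            coords = frame.coordinates @ rot.T
            vol = np.prod(coords.max(0) - coords.min(0))
            assert vol_aligned <= vol * 1.25   # box is near-minimal, not exact

    def test_com_moved_to_origin(self):
        frame, topo = self._cloud(seed=2)
        aligned, _ = fg.align_to_principal_axes(frame, topo)
        com = np.average(aligned.coordinates, axis=0, weights=topo.masses)
        np.testing.assert_allclose(com, 0.0, atol=1e-9)


def _point_topology(names_kinds, resname_by_kind=None):
    resnames = {"receptor": "GLY", "ligand": "LIG", "water": "WAT"}
    atoms, kinds = [], []
    copy = 0
    rid = 0
    for element, kind in names_kinds:
        rid += 1
        if kind == "ligand":
            copy += 1
        atoms.append(fg.AtomRecord(
            serial=rid, name=element, element=element,
            residue_name=resnames[kind], residue_id=rid,
            chain_or_copy=str(copy) if kind == "ligand" else "A"))
        kinds.append(kind)
    return fg.Topology(atoms=atoms, molecule_kinds=kinds,
                       n_ligand_copies=copy)


class TestAssembleBox:
    def _receptor(self):
        topo = _point_topology([("C", "receptor")])
        return fg.Frame(time_ns=0.0, coordinates=np.zeros((1, 3))), topo

    def _template(self, positions, kinds=None, box=4.0):
        kinds = kinds or ["water"] * len(positions)
        topo = _point_topology([("O", k) for k in kinds])
        frame = fg.Frame(time_ns=0.0, coordinates=np.asarray(positions,
                                                             dtype=float),
                         box_lengths=[box] * 3)
        return frame, topo

    def test_clashing_molecule_removed_whole(self):
        rframe, rtopo = self._receptor()
        # single tile centred on the receptor puts this water at 0.5 A
        tframe, ttopo = self._template([[2.5, 2.0, 2.0]], box=4.0)
        frame, topo, report = fg.assemble_multicopy_box(
            rframe, rtopo, tframe, ttopo, shell=2.0, clash=1.0, align=False)
        assert report.n_molecules_removed_clash >= 1
        total_molecules = np.prod(report.n_tiles)
        assert len(topo) == 1 + (total_molecules
                                 - report.n_molecules_removed_clash)

    def test_no_clash_conserves_every_tiled_atom(self):
        rframe, rtopo = self._receptor()
        # lattice waters land on odd coordinates, all > 1 A from the origin
        tframe, ttopo = self._template([[1.0, 1.0, 1.0]], box=4.0)
        frame, topo, report = fg.assemble_multicopy_box(
            rframe, rtopo, tframe, ttopo, shell=6.0, clash=1.0, align=False)
        assert report.n_molecules_removed_clash == 0
        assert len(topo) == 1 + int(np.prod(report.n_tiles))

    def test_tile_counts_match_ceil_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            extent = rng.uniform(5, 60, 3)
            shell = rng.uniform(5, 25)
            box = rng.uniform(3, 30, 3)
            counts = tiling_counts(extent, shell, box)
            oracle = tuple(int(np.ceil((extent[k] + 2 * shell) / box[k]))
                           for k in range(3))
            assert counts == oracle

    def test_clash_pruning_order_independent(self):
        rng = np.random.default_rng(8)
        positions = rng.uniform(0, 6, (6, 3))
        rframe, rtopo = self._receptor()
        frame1, topo1, _ = fg.assemble_multicopy_box(
            rframe, rtopo, *self._template(positions, box=6.0),
            shell=3.0, clash=2.0, align=False)
        perm = rng.permutation(6)
        frame2, topo2, _ = fg.assemble_multicopy_box(
            rframe, rtopo, *self._template(positions[perm], box=6.0),
            shell=3.0, clash=2.0, align=False)
        set1 = {tuple(np.round(c, 6)) for c in frame1.coordinates}
        set2 = {tuple(np.round(c, 6)) for c in frame2.coordinates}
        assert set1 == set2

    def test_oversized_template_is_placement_error(self):
        rframe, rtopo = self._receptor()
        tframe, ttopo = self._template([[1.0, 1.0, 1.0]], box=100.0)
        with pytest.raises(PlacementError):
            fg.assemble_multicopy_box(rframe, rtopo, tframe, ttopo,
                                      shell=2.0, align=False)

    def test_empty_template_rejected(self):
        rframe, rtopo = self._receptor()
        topo = fg.Topology(atoms=[], molecule_kinds=[])
        tframe = fg.Frame(time_ns=0.0, coordinates=np.zeros((0, 3)),
                          box_lengths=[4, 4, 4])
        with pytest.raises(ValidationError):
            fg.assemble_multicopy_box(rframe, rtopo, tframe, topo)


class TestRepulsiveTerm:
    def _two_copy_topology(self):
        spec = [("C", "receptor"), ("N", "ligand"), ("N", "ligand")]
        return _point_topology(spec)

    def test_central_atom_retyped_by_element(self):
        topo = self._two_copy_topology()
        out = fg.inject_repulsive_term(topo, "N")
        flagged = [a for a in out.atoms if a.is_repulsive_center]
        assert len(flagged) == 2
        assert all(a.amber_type == "N99" for a in flagged)

    def test_exactly_one_centre_per_copy(self):
        out = fg.inject_repulsive_term(self._two_copy_topology(), "N")
        for copy in out.copy_ids():
            idx = out.ligand_copy_indices(copy)
            assert sum(out.atoms[i].is_repulsive_center for i in idx) == 1

    def test_pair_energy_pure_repulsion_monotone(self):
        eps, rmin = 0.17, 1.824
        radii = np.linspace(1.0, 12.0, 50)
        energies = [lj_pair_energy(eps, rmin, eps, rmin, r,
                                   repulsive_only=True) for r in radii]
        assert all(e > 0 for e in energies)
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_normal_pair_unchanged(self):
        eps, rmin = 0.2, 1.8
        r = 3.6
        full = lj_pair_energy(eps, rmin, eps, rmin, r)
        assert full == pytest.approx(eps * ((2 * rmin / r) ** 12
                                            - 2 * (2 * rmin / r) ** 6))

    def test_absent_central_atom_selection_error(self):
        with pytest.raises(SelectionError):
            fg.inject_repulsive_term(self._two_copy_topology(), "ZZ")

    def test_unsupported_element_rejected(self):
        topo = _point_topology([("C", "receptor"), ("H", "ligand")])
        with pytest.raises(UnsupportedElementError):
            fg.inject_repulsive_term(topo, "H")

    def test_no_centre_pairs_leaves_energy_unchanged(self, energy_system):
        topo, frame = energy_system
        before = fg.nonbonded_inter_energy(frame, topo)
        topo2, _ = fg.make_energy_test_system(10, 15, seed=42)
        # flag a receptor atom only: still zero centre-centre pairs
        topo2.atoms[0].is_repulsive_center = True
        topo2._cache.clear()
        after = fg.nonbonded_inter_energy(frame, topo2)
        assert before.e_vdw == pytest.approx(after.e_vdw, abs=1e-12)
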