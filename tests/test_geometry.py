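"""Unwrapping, COM, membrane frame, and tilt/depth geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c1screen.errors import GeometryError
from c1screen.geometry import (
    LigandSpec,
    center_of_mass,
    ligand_orientation,
    make_whole,
    membrane_frame,
    minimum_image,
    orientation_samples,
    pbc_com_z,
)
from c1screen.trajio import AtomTable, Frame, Trajectory
from conftest import scenario_with


def _frame(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return Frame(time, np.asarray(box), np.asarray(coords, dtype=float))


class TestMakeWhole:
    def test_minimum_image_pair(self):
        fr = _frame([[0.1, 0, 0], [9.9, 0, 0]])
        out = make_whole(fr, [0, 1], [(0, 1)])
        assert np.allclose(out[1], [-0.1, 0, 0])
        assert np.isclose(np.linalg.norm(out[1] - out[0]), 0.2)

    def test_already_whole_is_identity(self):
        coords = [[1.0, 1.0, 1.0], [1.2, 1.0, 1.0], [1.4, 1.0, 1.0]]
        fr = _frame(coords)
        out = make_whole(fr, [0, 1, 2], [(0, 1), (1, 2)])
        assert np.array_equal(out, np.asarray(coords))

    def test_scattered_chain_matches_bfs_oracle(self, rng):
        # 20-atom chain with 0.15 nm bonds, scattered across periodic images
        box = np.array([5.0, 5.0, 5.0])
        true = np.cumsum(rng.normal(0, 0.15 / np.sqrt(3), (20, 3)), axis=0) + 2.5
        scattered = np.mod(true + rng.integers(-3, 4, (20, 3)) * box, box)
        bonds = [(i, i + 1) for i in range(19)]
        fr = _frame(scattered, box)
        out = make_whole(fr, np.arange(20), bonds)
        d = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert (d < box[0] / 2).all()

        # independent oracle: sequential minimum-image accumulation
        oracle = scattered.copy()
        for i in range(1, 20):
            oracle[i] = oracle[i - 1] + minimum_image(oracle[i] - oracle[i - 1], box)
        assert np.allclose(out, oracle)

    def test_disconnected_graph_lists_components(self):
        fr = _frame([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(GeometryError, match="components"):
            make_whole(fr, [0, 1, 2], [(0, 1)])


class TestCenterOfMass:
    def test_symmetric_pair(self):
        com = center_of_mass([[0, 0, 0], [0, 0, 2]], [1.0, 1.0])
        assert np.allclose(com, [0, 0, 1])

    def test_single_atom(self):
        assert np.allclose(center_of_mass([[1.5, 2.5, 3.5]], [12.0]), [1.5, 2.5, 3.5])

    def test_random_against_direct_sum(self, rng):
        coords = rng.uniform(-5, 5, (100, 3))
        masses = rng.uniform(0.5, 40, 100)
        expected = np.zeros(3)
        for x, m in zip(coords, masses):
            expected += m * x
        expected /= masses.sum()
        assert np.allclose(center_of_mass(coords, masses), expected)

    def test_zero_mass_raises(self):
        with pytest.raises(GeometryError):
            center_of_mass([[0, 0, 0]], [0.0])


class TestMembraneFrame:
    def _bilayer(self, z_center, box=(4.0, 4.0, 10.0)):
        zs = z_center + np.array([-2.0, -1.0, 1.0, 2.0])
        coords = np.column_stack([np.ones(4), np.ones(4), zs])
        atoms = AtomTable.from_names(["C"] * 4, ["LIP"] * 4, [1, 1, 2, 2])
        return _frame(coords, box), atoms

    def test_symmetric_bilayer_center(self):
        fr, atoms = self._bilayer(5.0)
        mem = membrane_frame(fr, np.arange(4), atoms.mass)
        assert np.isclose(mem.z_center, 5.0)

    def test_translation_equivariance(self):
        fr, atoms = self._bilayer(4.0)
        fr2 = _frame(fr.coords + [0, 0, 1.0], fr.box)
        m1 = membrane_frame(fr, np.arange(4), atoms.mass)
        m2 = membrane_frame(fr2, np.arange(4), atoms.mass)
        assert np.isclose(m2.z_center - m1.z_center, 1.0)

    def test_generator_center_recovered(self):
        traj, groups, gt = scenario_with("hmi_like", n_waters=10, n_ions=0, n_frames=10)
        z_mid = traj.frames[0].box[2] / 2
        for fr in traj.frames:
            mem = membrane_frame(fr, groups["lipids"], traj.atoms.mass)
            assert abs(mem.z_center - z_mid) < 0.05

    def test_empty_group_raises(self):
        fr, atoms = self._bilayer(5.0)
        with pytest.raises(GeometryError):
            membrane_frame(fr, np.array([], dtype=int), atoms.mass)

    def test_pbc_com_z_wraps(self):
        # bilayer straddling the z boundary: circular mean finds it
        z = np.array([9.6, 9.8, 0.2, 0.4])
        assert np.isclose(pbc_com_z(z, np.ones(4), 10.0) % 10.0, 0.0, atol=1e-9)


def _toy_ligand(axis, oh_z, box=(10.0, 10.0, 10.0), z_center=5.0):
    """Two-atom axis ligand + OH marker at z_center + oh_z; returns sample."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    oh = np.array([5.0, 5.0, z_center + oh_z])
    tail = oh - 0.5 * axis
    head = oh
    coords = np.array([tail, head])
    atoms = AtomTable.from_names(["C1", "O1"], ["LIG"] * 2, [1, 1])
    fr = _frame(coords, box)
    spec = LigandSpec(
        resname="LIG",
        n_copies=1,
        all_atoms=[np.array([0, 1])],
        axis_tail=[np.array([0])],
        axis_head=[np.array([1])],
        oh_group=[np.array([1])],
        bonds=[[(0, 1)]],
    )
    from c1screen.geometry import MembraneFrame

    mem = MembraneFrame(z_center=z_center, box=np.asarray(box))
    return ligand_orientation(fr, spec, 0, mem, atoms.mass)


class TestLigandOrientation:
    def test_aligned_upper_leaflet(self):
        s = _toy_ligand([0, 0, 1], oh_z=1.6)
        assert np.isclose(s.theta, 0.0, atol=1e-9)
        assert np.isclose(s.depth, 1.6)
        assert s.leaflet == "upper"

    def test_mirrored_ligand_folds_to_same_sample(self):
        s = _toy_ligand([0, 0, -1], oh_z=-1.6)
        assert np.isclose(s.theta, 0.0, atol=1e-9)
        assert np.isclose(s.depth, 1.6)
        assert s.leaflet == "lower"

    def test_45_degree_axis_matches_arccos(self):
        s = _toy_ligand([1, 0, 1], oh_z=1.6)
        assert np.isclose(s.theta, 45.0)

    def test_zero_length_axis_raises(self):
        atoms = AtomTable.from_names(["C1", "O1"], ["LIG"] * 2, [1, 1])
        fr = _frame([[5, 5, 6.0], [5, 5, 6.0]])
        spec = LigandSpec(
            resname="LIG",
            n_copies=1,
            all_atoms=[np.array([0, 1])],
            axis_tail=[np.array([0])],
            axis_head=[np.array([1])],
            oh_group=[np.array([1])],
        )
        from c1screen.geometry import MembraneFrame

        with pytest.raises(GeometryError, match="axis"):
            ligand_orientation(
                fr, spec, 0, MembraneFrame(5.0, np.array([10.0, 10.0, 10.0])), atoms.mass
            )


class TestTrajectorySymmetries:
    def _samples(self, traj, groups, spec):
        return orientation_samples(traj, spec, groups["lipids"])

    def test_leaflet_mirror_invariance(self, hmi_small):
        traj, groups, spec, _ = hmi_small
        ref = self._samples(traj, groups, spec)
        mirrored = Trajectory(
            atoms=traj.atoms,
            frames=[
                Frame(
                    f.time,
                    f.box,
                    np.mod(
                        np.column_stack(
                            [f.coords[:, 0], f.coords[:, 1], f.box[2] - f.coords[:, 2]]
                        ),
                        f.box,
                    ),
                )
                for f in traj.frames
            ],
        )
        mir = self._samples(mirrored, groups, spec)
        for a, b in zip(ref, mir):
            assert abs(a.theta - b.theta) < 1e-8
            assert abs(a.depth - b.depth) < 1e-8
            assert a.leaflet != b.leaflet

    def test_rigid_translation_invariance(self, hmi_small):
        traj, groups, spec, _ = hmi_small
        ref = self._samples(traj, groups, spec)
        shift = np.array([1.3, -0.7, 2.1])
        moved = Trajectory(
            atoms=traj.atoms,
            frames=[
                Frame(f.time, f.box, np.mod(f.coords + shift, f.box))
                for f in traj.frames
            ],
        )
        out = self._samples(moved, groups, spec)
        for a, b in zip(ref, out):
            assert abs(a.theta - b.theta) < 1e-8
            assert abs(a.depth - b.depth) < 1e-8

    @settings(max_examples=5, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_sample_ranges(self, seed):
        traj, groups, gt = scenario_with(
            "hmi_like", seed=seed, n_waters=10, n_ions=0, n_frames=5
        )
        spec = LigandSpec.from_selection_groups(groups, "LIG", 4)
        box_z = traj.frames[0].box[2]
        for s in orientation_samples(traj, spec, groups["lipids"]):
            assert 0.0 <= s.theta <= 180.0
            assert 0.0 <= s.depth <= box_z / 2
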