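"""Dot-surface SASA: analytic sphere and cap oracles, occlusion monotonicity,
rotation invariance, and block statistics."""

import numpy as np
import pytest

from c1screen.errors import SelectionError
from c1screen.geometry import LigandSpec
from c1screen.sasa import (
    SasaSettings,
    fibonacci_sphere,
    group_sasa_block_stats,
    shrake_rupley,
)
from c1screen.trajio import AtomTable, Frame, Trajectory

R_O = 0.152  # oxygen vdW radius, nm
PROBE = 0.14
BIG = R_O + PROBE


def _frame(coords, box=(10.0, 10.0, 10.0)):
    return Frame(0.0, np.asarray(box, dtype=float), np.asarray(coords, dtype=float))


def test_fibonacci_lattice_is_unit_and_deterministic():
    dots = fibonacci_sphere(960)
    assert np.allclose(np.linalg.norm(dots, axis=1), 1.0)
    assert np.array_equal(dots, fibonacci_sphere(960))


def test_isolated_sphere_analytic_area():
    fr = _frame([[5.0, 5.0, 5.0]])
    area = shrake_rupley(fr, [0], [], np.array([R_O]), SasaSettings())[0]
    exact = 4 * np.pi * BIG**2  # ~1.071 nm^2
    assert abs(area - exact) <= exact / 960
    assert np.isclose(exact, 1.0715, atol=5e-4)


def test_fully_buried_atom_zero_area():
    # cage of large occluders surrounding the central atom
    shell = fibonacci_sphere(60) * 0.25 + 5.0
    coords = np.vstack([[5.0, 5.0, 5.0], shell])
    radii = np.concatenate([[R_O], np.full(60, 0.3)])
    fr = _frame(coords)
    area = shrake_rupley(fr, [0], np.arange(1, 61), radii, SasaSettings())[0]
    assert area == 0.0


@pytest.mark.parametrize("d", np.linspace(0.05, 2 * BIG - 0.02, 12))
def test_two_sphere_cap_formula(d):
    rng = np.random.default_rng(int(d * 10_000))
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    fr = _frame([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0] + d * u])
    area = shrake_rupley(fr, [0], [1], np.array([R_O, R_O]), SasaSettings())[0]
    h = BIG - d / 2  # cap height cut by the identical expanded sphere
    exact = 4 * np.pi * BIG**2 - 2 * np.pi * BIG * h
    assert abs(area - exact) <= 5 * (4 * np.pi * BIG**2) / 960


def test_doubling_dots_converges():
    fr = _frame([[5.0, 5.0, 5.0], [5.0, 5.0, 5.3]])
    radii = np.array([R_O, R_O])
    a1 = shrake_rupley(fr, [0], [1], radii, SasaSettings(n_dots=960))[0]
    a2 = shrake_rupley(fr, [0], [1], radii, SasaSettings(n_dots=1920))[0]
    assert abs(a1 - a2) <= 5 * (4 * np.pi * BIG**2) / 960
    assert a1 >= 0 and a2 >= 0


def test_adding_occluders_never_increases_area(rng):
    center = np.array([[5.0, 5.0, 5.0]])
    occ = rng.uniform(4.5, 5.5, (15, 3))
    coords = np.vstack([center, occ])
    radii = np.full(16, R_O)
    fr = _frame(coords)
    prev = np.inf
    for k in range(0, 16):
        area = shrake_rupley(fr, [0], np.arange(1, k + 1), radii, SasaSettings(n_dots=240))[0]
        assert area <= prev + 1e-12
        prev = area


def test_rigid_rotation_invariance(rng):
    pts = rng.uniform(4.6, 5.4, (8, 3))
    radii = np.full(8, R_O)
    fr = _frame(pts, box=(50.0, 50.0, 50.0))
    a0 = shrake_rupley(fr, np.arange(8), np.arange(8), radii, SasaSettings()).sum()
    # random rotation about the cluster centroid
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    centroid = pts.mean(axis=0)
    rotated = (pts - centroid) @ q.T + centroid
    a1 = shrake_rupley(_frame(rotated, box=(50.0, 50.0, 50.0)), np.arange(8),
                       np.arange(8), radii, SasaSettings()).sum()
    assert abs(a0 - a1) <= 8 * 5 * (4 * np.pi * BIG**2) / 960


def test_missing_radius_named():
    fr = _frame([[5.0, 5.0, 5.0]])
    with pytest.raises(SelectionError, match="0"):
        shrake_rupley(fr, [0], [], np.array([np.nan]), SasaSettings())


def test_periodic_occlusion_across_boundary():
    # occluder across the box boundary still shadows the atom
    fr = _frame([[0.05, 5.0, 5.0], [9.95, 5.0, 5.0]], box=(10.0, 10.0, 10.0))
    radii = np.array([R_O, R_O])
    a = shrake_rupley(fr, [0], [1], radii, SasaSettings())[0]
    assert a < 4 * np.pi * BIG**2 * 0.999


def _vacuum_ligand_traj(n_frames=6):
    """Four identical, far-separated two-atom 'ligands' in vacuum."""
    names, resnames, resids, coords = [], [], [], []
    for c in range(4):
        names += ["C1", "O1"]
        resnames += ["LIG"] * 2
        resids += [c + 1] * 2
        base = np.array([2.0 + 4.0 * c, 2.0, 2.0])
        coords += [base, base + [0, 0, 0.3]]
    atoms = AtomTable.from_names(names, resnames, resids)
    coords = np.asarray(coords)
    frames = [Frame(float(t), np.array([20.0, 20.0, 20.0]), coords) for t in range(n_frames)]
    traj = Trajectory(atoms=atoms, frames=frames)
    spec = LigandSpec(
        resname="LIG",
        n_copies=4,
        all_atoms=[np.array([2 * c, 2 * c + 1]) for c in range(4)],
        axis_tail=[np.array([2 * c]) for c in range(4)],
        axis_head=[np.array([2 * c + 1]) for c in range(4)],
        oh_group=[np.array([2 * c + 1]) for c in range(4)],
        oono_group=[np.array([2 * c]) for c in range(4)],
    )
    return traj, spec


def test_vacuum_ligand_constant_area_zero_sd():
    traj, spec = _vacuum_ligand_traj()
    ba = group_sasa_block_stats(traj, spec, "oh", SasaSettings(n_dots=240), n_blocks=3)
    assert ba.sd == 0.0
    assert ba.grand_mean > 0.0


def test_exposed_versus_caged_group_ordering():
    """A hydroxy oxygen in the open has strictly larger SASA than the same
    oxygen caged by membrane-core-like occluders (constructed ordering)."""
    shell = fibonacci_sphere(40) * 0.5 + np.array([5.0, 5.0, 5.0])
    coords_caged = np.vstack([[5.0, 5.0, 5.0], shell])
    coords_open = np.vstack([[5.0, 5.0, 5.0], shell + 5.0])
    radii = np.concatenate([[R_O], np.full(40, 0.17)])
    caged = shrake_rupley(_frame(coords_caged, box=(20.0,) * 3), [0],
                          np.arange(41), radii, SasaSettings())[0]
    open_ = shrake_rupley(_frame(coords_open, box=(20.0,) * 3), [0],
                          np.arange(41), radii, SasaSettings())[0]
    assert open_ > caged


def test_block_scheme_from_generator(hmi_small):
    traj, groups, spec, _ = hmi_small
    ba = group_sasa_block_stats(traj, spec, "oh", SasaSettings(n_dots=96), n_blocks=5)
    # 60 frames at 7.5 ns -> 12-frame blocks of 90 ns each
    assert ba.n_blocks == 5
    assert np.isclose(ba.block_duration, 12 * 7500.0)
    assert ba.grand_mean > 0


def test_cross_check_against_mdtraj(rng):
    """Independent dot-surface implementation agrees on a non-periodic
    oxygen cluster (different dot lattices, same algorithm)."""
    md = pytest.importorskip("mdtraj")
    pts = rng.uniform(0, 0.8, (6, 3)) + 2.0
    top = md.Topology()
    res = top.add_residue("HOH", top.add_chain())
    for _ in range(6):
        top.add_atom("O", md.element.oxygen, res)
    t = md.Trajectory(xyz=pts[None].astype(np.float32), topology=top)
    t.unitcell_lengths = np.array([[10.0, 10.0, 10.0]])
    t.unitcell_angles = np.array([[90.0, 90.0, 90.0]])
    theirs = md.shrake_rupley(t, probe_radius=PROBE, n_sphere_points=960)[0]
    ours = shrake_rupley(
        _frame(pts), np.arange(6), np.arange(6), np.full(6, R_O), SasaSettings()
    )
    assert np.abs(ours - theirs).max() < 0.02
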