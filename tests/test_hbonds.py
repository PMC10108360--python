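"""Hydrogen-bond geometry, grid/brute equivalence, and block statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c1screen.blocks import block_average
from c1screen.errors import AnalysisError, SelectionError
from c1screen.geometry import LigandSpec, minimum_image
from c1screen.hbonds import (
    HBondCriterion,
    detect_hbonds,
    hbond_block_stats,
    lipid_partner,
    water_partner,
)
from c1screen.trajio import AtomTable, Frame, Trajectory


def _frame(coords, box=(6.0, 6.0, 6.0)):
    return Frame(0.0, np.asarray(box, dtype=float), np.asarray(coords, dtype=float))


def _oracle(coords, box, donors, acceptors, crit):
    """Independent exhaustive search, written against the criterion only."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    found = set()
    for d, h in donors:
        for a in acceptors:
            if a == d or a == h:
                continue
            da = minimum_image(coords[a] - coords[d], box)
            if np.linalg.norm(da) > crit.r_da_max:
                continue
            dh = minimum_image(coords[h] - coords[d], box)
            cosv = dh @ da / (np.linalg.norm(dh) * np.linalg.norm(da))
            if np.degrees(np.arccos(np.clip(cosv, -1, 1))) <= crit.angle_max:
                found.add((d, h, a))
    return sorted(found)


def test_ideal_geometry_counts_one_bond():
    # H exactly on the D->A segment: angle 0, r = 0.30
    fr = _frame([[1.0, 1, 1], [1.1, 1, 1], [1.3, 1, 1]])
    assert detect_hbonds(fr, [(0, 1)], [2]) == [(0, 1, 2)]


def test_just_outside_distance_cutoff():
    fr = _frame([[1.0, 1, 1], [1.1, 1, 1], [1.36, 1, 1]])
    assert detect_hbonds(fr, [(0, 1)], [2]) == []


def test_angle_cutoff_boundary():
    # place A at 35 degrees off the D-H axis, within distance
    ang = np.radians(35.0)
    a = [1.0 + 0.3 * np.cos(ang), 1.0 + 0.3 * np.sin(ang), 1.0]
    fr = _frame([[1.0, 1, 1], [1.1, 1, 1], a])
    assert detect_hbonds(fr, [(0, 1)], [2]) == []
    assert detect_hbonds(fr, [(0, 1)], [2], HBondCriterion(angle_max=40.0)) == [(0, 1, 2)]


def test_donor_own_acceptor_excluded():
    fr = _frame([[1.0, 1, 1], [1.1, 1, 1]])
    assert detect_hbonds(fr, [(0, 1)], [0, 1]) == []


def _random_config(rng, n=500, box=4.0):
    coords = rng.uniform(0, box, (n, 3))
    d_idx = rng.choice(n, n // 6, replace=False)
    donors = []
    for d in d_idx:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        h = (d + 1) % n
        coords[h] = coords[d] + 0.1 * u
        donors.append((int(d), int(h)))
    acceptors = rng.choice(n, 2 * n // 5, replace=False)
    return coords, donors, acceptors


@pytest.mark.parametrize("seed", range(5))
def test_grid_equals_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    coords, donors, acceptors = _random_config(rng)
    fr = _frame(coords, (4.0, 4.0, 4.0))
    crit = HBondCriterion()
    grid = detect_hbonds(fr, donors, acceptors, crit, method="grid")
    brute = detect_hbonds(fr, donors, acceptors, crit, method="brute")
    oracle = _oracle(coords, (4.0, 4.0, 4.0), donors, [int(a) for a in acceptors], crit)
    assert grid == brute == oracle


def test_periodic_wraparound_detected():
    fr = _frame([[0.05, 1, 1], [0.15, 1, 1], [5.80, 1, 1]])
    # D at x=0.05, A at x=5.80 in a 6 nm box: minimum image r = 0.25
    assert detect_hbonds(fr, [(0, 1)], [2]) == []  # H points away (+x), angle 180
    fr2 = _frame([[0.05, 1, 1], [5.95, 1, 1], [5.80, 1, 1]])
    assert detect_hbonds(fr2, [(0, 1)], [2]) == [(0, 1, 2)]


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_cutoff_monotonicity(seed):
    rng = np.random.default_rng(seed)
    coords, donors, acceptors = _random_config(rng, n=100)
    fr = _frame(coords, (4.0, 4.0, 4.0))
    small = detect_hbonds(fr, donors, acceptors, HBondCriterion(0.3, 20.0))
    large = detect_hbonds(fr, donors, acceptors, HBondCriterion(0.4, 35.0))
    assert set(small) <= set(large)


def test_donor_hydrogen_must_be_bonded_in_spec():
    with pytest.raises(SelectionError, match="not bonded"):
        LigandSpec(
            resname="LIG",
            n_copies=1,
            all_atoms=[np.array([0, 1, 2])],
            axis_tail=[np.array([0])],
            axis_head=[np.array([1])],
            oh_group=[np.array([1, 2])],
            donors=[[(1, 2)]],
            bonds=[[(0, 1)]],  # 1-2 not bonded
        )


def _two_group_system():
    """One ligand with separated OH and carbonyl sites plus two waters.

    Water W1 donates to the carbonyl oxygen only; the hydroxy group is far
    from everything. Exercises group separation (no cross-contamination).
    """
    # ligand: C(tail) O1 H1 (oh, far corner) OE (carbonyl)
    names = ["C1", "O1", "HO1", "OE1", "OW", "HW1", "HW2", "OW", "HW1", "HW2"]
    resnames = ["LIG"] * 4 + ["SOL"] * 6
    resids = [1, 1, 1, 1, 2, 2, 2, 3, 3, 3]
    atoms = AtomTable.from_names(names, resnames, resids)
    coords = np.array(
        [
            [1.0, 1.0, 1.0],  # C1
            [1.0, 1.0, 1.2],  # O1
            [1.0, 1.0, 1.3],  # HO1
            [3.0, 3.0, 3.0],  # OE1
            [3.0, 3.0, 3.3],  # OW of W1: donates straight down to OE1
            [3.0, 3.0, 3.2],  # HW1 on the O->OE axis
            [3.1, 3.0, 3.4],  # HW2 away
            [5.0, 5.0, 5.0],  # W2 far away
            [5.1, 5.0, 5.0],
            [5.0, 5.1, 5.0],
        ]
    )
    frames = [Frame(float(t), np.array([6.0, 6.0, 6.0]), coords) for t in range(5)]
    traj = Trajectory(atoms=atoms, frames=frames)
    spec = LigandSpec(
        resname="LIG",
        n_copies=1,
        all_atoms=[np.arange(4)],
        axis_tail=[np.array([0])],
        axis_head=[np.array([1])],
        oh_group=[np.array([1, 2])],
        oono_group=[np.array([3])],
        donors=[[(1, 2)]],
        acceptors=[np.array([1, 3])],
    )
    return traj, spec


def test_group_separation_oh_vs_oono():
    traj, spec = _two_group_system()
    wp = water_partner(traj.atoms, np.arange(4, 10))
    oh = hbond_block_stats(traj, spec, "oh", wp, n_blocks=5)
    oono = hbond_block_stats(traj, spec, "oono", wp, n_blocks=5)
    assert oh.grand_mean == 0.0
    assert oono.grand_mean == 1.0
    assert oono.sd == 0.0


def test_constant_series_zero_sd():
    ba = block_average(np.full(100, 2.0), np.arange(100.0), 5)
    assert ba.grand_mean == 2.0
    assert ba.sd == 0.0


def test_block_scheme_1500_units_5_blocks():
    """A 1500-time-unit analyzed span in 5 blocks gives 300-unit blocks."""
    times = np.arange(1500.0)
    ba = block_average(np.ones(1500), times, 5)
    assert ba.n_blocks == 5
    assert np.isclose(ba.block_duration, 300.0, rtol=1e-3)
    assert ba.n_frames_dropped == 0


def test_remainder_frames_dropped():
    ba = block_average(np.arange(17.0), np.arange(17.0), 5)
    assert ba.n_frames_used == 15
    assert ba.n_frames_dropped == 2


def test_fewer_frames_than_blocks_raises():
    with pytest.raises(AnalysisError):
        block_average([1.0, 2.0], [0.0, 1.0], 5)


def test_grand_mean_is_mean_of_block_means(rng):
    vals = rng.normal(size=200)
    ba = block_average(vals, np.arange(200.0), 5)
    assert np.isclose(ba.grand_mean, ba.block_means.mean())
    assert ba.sd >= 0


def test_injected_bernoulli_rate_recovered(hmi_small):
    traj, groups, spec, gt = hmi_small
    wp = water_partner(traj.atoms, groups["water"])
    ba = hbond_block_stats(traj, spec, "oh", wp, n_blocks=5)
    p = gt["config"]["hbond_rate"]
    n = gt["hbond_event"].size
    se = np.sqrt(p * (1 - p) / n)
    assert abs(ba.grand_mean - p) <= 3 * se + abs(gt["hbond_event"].mean() - p)


def test_lipid_partner_oxygen_acceptors(hmi_small):
    traj, groups, _, _ = hmi_small
    lp = lipid_partner(traj.atoms, groups["lipids"])
    assert len(lp.donors) == 0
    assert all(traj.atoms.element[a] == "O" for a in lp.acceptors)
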