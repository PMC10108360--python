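"""Geometric hydrogen-bond detection and per-molecule block statistics.

A bond is counted between donor pair (D, H) and acceptor A when the
minimum-image donor-acceptor distance r(D,A) <= r_da_max and the H-D-A
angle <= angle_max. The defaults (0.35 nm, 30°) are the conventional
geometric criterion of MD analysis toolchains; both are configuration keys
echoed into every report. Detection uses a periodic cell list and is
exactly equivalent to the exhaustive pair search.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .blocks import BlockAverage, block_average
from .errors import ConfigError, SelectionError
from .geometry import LigandSpec, minimum_image
from .trajio import AtomTable, Frame, Trajectory

__all__ = [
    "HBondCriterion",
    "HBondPartner",
    "detect_hbonds",
    "hbond_block_stats",
    "water_partner",
    "lipid_partner",
    "BlockAverage",
]

DEFAULT_R_DA_MAX = 0.35  # nm
DEFAULT_ANGLE_MAX = 30.0  # degrees, H-D-A


@dataclass
class HBondCriterion:
    r_da_max: float = DEFAULT_R_DA_MAX
    angle_max: float = DEFAULT_ANGLE_MAX

    def __post_init__(self) -> None:
        if self.r_da_max <= 0:
            raise ConfigError("r_da_max must be positive")
        if not (0 < self.angle_max < 90):
            raise ConfigError("angle_max must be in (0, 90) degrees")


@dataclass
class HBondPartner:
    """Donor pairs and acceptor atoms of a partner group (water or lipid)."""

    label: str
    donors: np.ndarray  # (n, 2) int: (D, H)
    acceptors: np.ndarray  # (m,) int


def _angle_ok(
    coords: np.ndarray, box: np.ndarray, d: int, h: int, a_idx: np.ndarray, cos_min: float
) -> np.ndarray:
    dh = minimum_image(coords[h] - coords[d], box)
    da = minimum_image(coords[a_idx] - coords[d], box)
    num = da @ dh
    den = np.linalg.norm(dh) * np.linalg.norm(da, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(den > 0, num / den, -1.0)
    return cos >= cos_min


def _detect_brute(coords, box, donors, acceptors, crit: HBondCriterion):
    cos_min = float(np.cos(np.radians(crit.angle_max)))
    out = []
    acceptors = np.asarray(acceptors, dtype=int)
    for d, h in donors:
        a_ok = acceptors[(acceptors != d) & (acceptors != h)]
        if not len(a_ok):
            continue
        disp = minimum_image(coords[a_ok] - coords[d], box)
        r = np.linalg.norm(disp, axis=1)
        close = a_ok[r <= crit.r_da_max]
        if not len(close):
            continue
        good = close[_angle_ok(coords, box, d, h, close, cos_min)]
        out.extend((int(d), int(h), int(a)) for a in good)
    return sorted(set(out))


def _cell_list(coords, box, indices, cutoff, positions=None):
    nc = np.maximum(1, np.floor(box / cutoff).astype(int))
    wrapped = np.mod(coords[indices] if positions is None else positions, box)
    cell = np.minimum((wrapped / box * nc).astype(int), nc - 1)
    table: dict[tuple[int, int, int], list[int]] = {}
    for local, c in enumerate(map(tuple, cell)):
        table.setdefault(c, []).append(int(indices[local]))
    return nc, table


def detect_hbonds(
    frame: Frame,
    donors,
    acceptors,
    crit: HBondCriterion | None = None,
    method: str = "grid",
) -> list[tuple[int, int, int]]:
    """All (D, H, A) hydrogen-bond triples in one frame.

    A donor's own atoms are excluded as acceptors (A != D and A != H); each
    triple is reported at most once, in sorted order. ``method`` selects the
    cell-list path ("grid", default) or the exhaustive pair search
    ("brute"); both return identical triples.
    """
    crit = crit or HBondCriterion()
    donors = [(int(d), int(h)) for d, h in donors]
    acceptors = np.asarray(acceptors, dtype=int)
    if not donors or not len(acceptors):
        return []
    coords, box = frame.coords, frame.box
    if method == "brute" or (np.floor(box / crit.r_da_max) < 3).any():
        # cells wrap onto themselves in a small box; exhaustive search is exact
        return _detect_brute(coords, box, donors, acceptors, crit)
    if method != "grid":
        raise ConfigError(f"unknown detection method {method!r}")

    cos_min = float(np.cos(np.radians(crit.angle_max)))
    # iterate over the smaller side so ligand-sized selections stay cheap
    if len(donors) <= len(acceptors):
        return _grid_by_donor(coords, box, donors, acceptors, crit, cos_min)
    return _grid_by_acceptor(coords, box, donors, acceptors, crit, cos_min)


def _neighbor_candidates(table, nc, pos, box) -> list[int]:
    wrapped = np.mod(pos, box)
    cell = np.minimum((wrapped / box * nc).astype(int), nc - 1)
    cand: list[int] = []
    for off in product((-1, 0, 1), repeat=3):
        key = tuple((cell + off) % nc)
        cand.extend(table.get(key, ()))
    return cand


def _grid_by_donor(coords, box, donors, acceptors, crit, cos_min):
    nc, table = _cell_list(coords, box, acceptors, crit.r_da_max)
    out = []
    for d, h in donors:
        cand = _neighbor_candidates(table, nc, coords[d], box)
        cand_arr = np.asarray(sorted(set(cand)), dtype=int)
        cand_arr = cand_arr[(cand_arr != d) & (cand_arr != h)]
        if not len(cand_arr):
            continue
        disp = minimum_image(coords[cand_arr] - coords[d], box)
        r = np.linalg.norm(disp, axis=1)
        close = cand_arr[r <= crit.r_da_max]
        if not len(close):
            continue
        good = close[_angle_ok(coords, box, d, h, close, cos_min)]
        out.extend((int(d), int(h), int(a)) for a in good)
    return sorted(set(out))


def _grid_by_acceptor(coords, box, donors, acceptors, crit, cos_min):
    donors = np.asarray(donors, dtype=int)
    d_idx = donors[:, 0]
    # cell list over donor D atoms, keyed by donor-row index
    nc, table = _cell_list(coords, box, np.arange(len(donors)), crit.r_da_max,
                           positions=coords[d_idx])
    out = []
    for a in np.asarray(acceptors, dtype=int):
        rows = _neighbor_candidates(table, nc, coords[a], box)
        if not rows:
            continue
        rows = np.asarray(sorted(set(rows)), dtype=int)
        dd, hh = donors[rows, 0], donors[rows, 1]
        keep = (dd != a) & (hh != a)
        dd, hh = dd[keep], hh[keep]
        if not len(dd):
            continue
        da = minimum_image(coords[a] - coords[dd], box)
        r = np.linalg.norm(da, axis=1)
        within = r <= crit.r_da_max
        dd, hh, da, r = dd[within], hh[within], da[within], r[within]
        if not len(dd):
            continue
        dh = minimum_image(coords[hh] - coords[dd], box)
        den = np.linalg.norm(dh, axis=1) * r
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(den > 0, (dh * da).sum(axis=1) / den, -1.0)
        good = cos >= cos_min
        out.extend(
            (int(d), int(h), int(a)) for d, h in zip(dd[good], hh[good])
        )
    return sorted(set(out))


def water_partner(atoms: AtomTable, water_group: np.ndarray) -> HBondPartner:
    """Build water donor pairs/acceptors from a 3-site water selection.

    Each water oxygen is a donor with its two following hydrogens (residue
    order) and an acceptor.
    """
    water_group = np.asarray(water_group, dtype=int)
    donors, acceptors = [], []
    i = 0
    while i < len(water_group):
        o = int(water_group[i])
        if atoms.element[o] != "O":
            raise SelectionError(
                f"water group atom {o} ({atoms.name[o]}) is not an oxygen where one "
                "was expected; water selections must list O,H,H per molecule"
            )
        if i + 2 >= len(water_group):
            raise SelectionError("truncated water molecule at the end of the selection")
        h1, h2 = int(water_group[i + 1]), int(water_group[i + 2])
        if atoms.element[h1] != "H" or atoms.element[h2] != "H":
            raise SelectionError(f"atoms {h1},{h2} after water oxygen {o} are not hydrogens")
        donors.extend([(o, h1), (o, h2)])
        acceptors.append(o)
        i += 3
    return HBondPartner(
        label="water",
        donors=np.asarray(donors, dtype=int),
        acceptors=np.asarray(acceptors, dtype=int),
    )


def lipid_partner(atoms: AtomTable, lipid_group: np.ndarray) -> HBondPartner:
    """Lipid partner: oxygens (head/ester) act as acceptors; no lipid donors."""
    lipid_group = np.asarray(lipid_group, dtype=int)
    acc = lipid_group[np.asarray([atoms.element[i] == "O" for i in lipid_group])]
    return HBondPartner(
        label="lipid", donors=np.empty((0, 2), dtype=int), acceptors=np.asarray(acc, dtype=int)
    )


def _ligand_sites(spec: LigandSpec, copy: int, group: str):
    """Donor pairs and acceptor atoms of one ligand copy's OH or OO/NO group.

    The hydroxy group donates and accepts; the ester/amide carbonyl oxygens
    accept only.
    """
    if group == "oh":
        if spec.oh_group is None or len(spec.oh_group[copy]) == 0:
            raise SelectionError(f"copy {copy} has no oh group")
        members = set(map(int, spec.oh_group[copy]))
    elif group == "oono":
        if spec.oono_group is None or len(spec.oono_group[copy]) == 0:
            raise SelectionError(f"copy {copy} has no oono group")
        members = set(map(int, spec.oono_group[copy]))
    else:
        raise ConfigError(f"unknown ligand group {group!r} (expected 'oh' or 'oono')")

    donors = []
    if group == "oh" and spec.donors:
        donors = [(d, h) for d, h in spec.donors[copy] if int(d) in members]
    acc_pool = (
        set(map(int, spec.acceptors[copy])) if len(spec.acceptors) else members
    )
    acceptors = np.asarray(sorted(members & acc_pool), dtype=int)
    return np.asarray(donors, dtype=int).reshape(-1, 2), acceptors


def count_hbonds_per_molecule(
    frame: Frame,
    spec: LigandSpec,
    group: str,
    partner: HBondPartner,
    crit: HBondCriterion | None = None,
) -> float:
    """Ligand-partner H-bonds in one frame, averaged over the ligand copies.

    Counts both directions: ligand group donating to partner acceptors and
    partner donors donating to ligand acceptors.
    """
    crit = crit or HBondCriterion()
    total = 0
    acc_union: list[np.ndarray] = []
    for c in range(spec.n_copies):
        lig_donors, lig_acceptors = _ligand_sites(spec, c, group)
        total += len(detect_hbonds(frame, lig_donors, partner.acceptors, crit))
        acc_union.append(lig_acceptors)
    # copies' acceptor sets are disjoint, so one partner-donor pass over the
    # union equals the per-copy sum
    all_acc = np.concatenate(acc_union) if acc_union else np.empty(0, dtype=int)
    if len(partner.donors) and len(all_acc):
        total += len(detect_hbonds(frame, partner.donors, all_acc, crit))
    return total / spec.n_copies


def hbond_block_stats(
    traj: Trajectory,
    spec: LigandSpec,
    group: str,
    partner: HBondPartner,
    crit: HBondCriterion | None = None,
    n_blocks: int = 5,
) -> BlockAverage:
    """Per-molecule H-bond count vs a partner group, with block statistics.

    Per frame the count is summed over the ligand copies and divided by the
    number of copies; the series is then split into ``n_blocks`` contiguous
    equal-duration blocks (grand mean, SD of block means).
    """
    series = [count_hbonds_per_molecule(fr, spec, group, partner, crit) for fr in traj.frames]
    return block_average(series, traj.times, n_blocks)
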