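"""Periodic-boundary-aware geometry: unwrapping, centers of mass, membrane
frame, ligand tilt angle and hydroxy depth.

Conventions
-----------
* The membrane normal is the box z axis (flat bilayer patch assumption).
* Each leaflet has an *outward* normal: +z for the upper leaflet, -z for
  the lower one (pointing from the bilayer center toward water). Tilt
  angles are measured against the outward normal of the leaflet hosting
  the ligand's hydroxy group, so that a correctly oriented ligand reads a
  small θ in either leaflet, while a flipped one reads θ near 180°.
* Depth is the leaflet-folded, nonnegative minimum-image z distance of the
  hydroxy-group COM from the bilayer COM.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, SelectionError
from .trajio import Frame, SelectionGroups

__all__ = [
    "minimum_image",
    "make_whole",
    "center_of_mass",
    "pbc_com_z",
    "MembraneFrame",
    "membrane_frame",
    "LigandSpec",
    "OrientationSample",
    "ligand_orientation",
    "orientation_samples",
]


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold displacement vector(s) into the minimum-image convention."""
    disp = np.asarray(disp, dtype=float)
    return disp - box * np.round(disp / box)


def make_whole(
    frame: Frame,
    molecule: np.ndarray,
    bonds: list[tuple[int, int]],
    root: int | None = None,
) -> np.ndarray:
    """Unwrap one molecule across periodic boundaries.

    ``molecule`` lists global atom indices; ``bonds`` are (global, global)
    pairs over those atoms. Starting from ``root`` (default: first listed
    atom), every bonded neighbour is placed at its minimum-image
    displacement from its already-placed parent. Returns the unwrapped
    (n_mol, 3) coordinates in molecule order; the root atom is unchanged.
    """
    molecule = np.asarray(molecule, dtype=int)
    local = {int(g): i for i, g in enumerate(molecule)}
    n = len(molecule)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        ia, ib = local.get(int(a)), local.get(int(b))
        if ia is None or ib is None:
            raise SelectionError(f"bond ({a},{b}) references atoms outside the molecule")
        adj[ia].append(ib)
        adj[ib].append(ia)

    out = frame.coords[molecule].astype(float).copy()
    start = 0 if root is None else local[int(root)]
    seen = np.zeros(n, dtype=bool)
    seen[start] = True
    queue = deque([start])
    while queue:
        i = queue.popleft()
        for j in adj[i]:
            if not seen[j]:
                out[j] = out[i] + minimum_image(out[j] - out[i], frame.box)
                seen[j] = True
                queue.append(j)
    if not seen.all():
        comps = _components(adj)
        raise GeometryError(
            f"bond graph is disconnected: components {[sorted(c) for c in comps]} "
            "(local indices)"
        )
    return out


def _components(adj: list[list[int]]) -> list[list[int]]:
    seen = [False] * len(adj)
    comps = []
    for s in range(len(adj)):
        if seen[s]:
            continue
        comp, queue = [], deque([s])
        seen[s] = True
        while queue:
            i = queue.popleft()
            comp.append(i)
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    queue.append(j)
        comps.append(comp)
    return comps


def pbc_com_z(z: np.ndarray, masses: np.ndarray, box_z: float) -> float:
    """Mass-weighted center along periodic z via the circular mean.

    Exactly equivariant under rigid translation modulo the box, so the
    bilayer center is well defined even when the membrane straddles the z
    boundary (the naive mean is not).
    """
    masses = np.asarray(masses, dtype=float)
    if masses.sum() <= 0:
        raise GeometryError("zero total mass in center-of-mass computation")
    ang = 2.0 * np.pi * np.asarray(z, dtype=float) / box_z
    s = float((masses * np.sin(ang)).sum())
    c = float((masses * np.cos(ang)).sum())
    if s * s + c * c < 1e-24:
        raise GeometryError("periodic center of mass undefined (uniform distribution)")
    return float(np.mod(np.arctan2(s, c) / (2.0 * np.pi), 1.0) * box_z)


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position. Coordinates must already be whole."""
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise GeometryError("zero total mass in center-of-mass computation")
    return (np.asarray(coords, dtype=float) * masses[:, None]).sum(axis=0) / total


@dataclass
class MembraneFrame:
    """Bilayer reference frame for one trajectory frame."""

    z_center: float  # nm, z of the lipid COM
    box: np.ndarray  # (3,)

    def outward_normal(self, leaflet: str) -> np.ndarray:
        if leaflet == "upper":
            return np.array([0.0, 0.0, 1.0])
        if leaflet == "lower":
            return np.array([0.0, 0.0, -1.0])
        raise ValueError(f"unknown leaflet {leaflet!r}")


def membrane_frame(frame: Frame, lipid_group: np.ndarray, masses: np.ndarray) -> MembraneFrame:
    """Locate the bilayer center along z.

    The normal is fixed to the box z axis; z_center is the periodic
    (circular-mean) z COM of the lipid group, well defined even when the
    bilayer straddles the z boundary.
    """
    lipid_group = np.asarray(lipid_group, dtype=int)
    if lipid_group.size == 0:
        raise GeometryError("empty lipid group")
    z_c = pbc_com_z(
        frame.coords[lipid_group, 2], np.asarray(masses)[lipid_group], frame.box[2]
    )
    return MembraneFrame(z_center=z_c, box=frame.box)


@dataclass
class LigandSpec:
    """Per-candidate atom groups, one entry per ligand copy.

    Groups are global atom-index arrays. ``axis_tail`` (core-ring atoms) and
    ``axis_head`` (hydroxy oxygen by default) define the central axis vector
    COM(head) - COM(tail). ``oh_group``/``oono_group`` may be ``None`` for
    control compounds lacking those moieties. ``donors`` are (D, H) pairs;
    ``acceptors`` are acceptor atoms. ``bonds`` (global pairs, per copy) let
    the analysis unwrap each copy across periodic boundaries.
    """

    resname: str
    n_copies: int
    all_atoms: list[np.ndarray]
    axis_tail: list[np.ndarray]
    axis_head: list[np.ndarray]
    oh_group: list[np.ndarray] | None = None
    oono_group: list[np.ndarray] | None = None
    donors: list[list[tuple[int, int]]] = field(default_factory=list)
    acceptors: list[np.ndarray] = field(default_factory=list)
    bonds: list[list[tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise SelectionError("n_copies must be >= 1")
        for name in ("all_atoms", "axis_tail", "axis_head"):
            grp = getattr(self, name)
            if len(grp) != self.n_copies:
                raise SelectionError(f"{name} must have one entry per copy")
            for c, idx in enumerate(grp):
                if len(idx) == 0:
                    raise SelectionError(f"{name} empty for copy {c}")
        for c in range(self.n_copies):
            if set(map(int, self.axis_tail[c])) & set(map(int, self.axis_head[c])):
                raise SelectionError(f"axis_tail and axis_head overlap in copy {c}")
        if self.bonds:
            for c, pairs in enumerate(self.donors or []):
                bondset = {frozenset(b) for b in self.bonds[c]}
                for d, h in pairs:
                    if frozenset((int(d), int(h))) not in bondset:
                        raise SelectionError(
                            f"donor hydrogen {h} not bonded to donor {d} in copy {c}"
                        )

    @classmethod
    def from_selection_groups(
        cls, groups: SelectionGroups, resname: str, n_copies: int
    ) -> "LigandSpec":
        """Reconstruct a spec from NDX groups named ``{resname}{i}_{label}``.

        Expected labels per copy i (1-based): all, tail, head; optional: oh,
        oono, donors (flattened D H D H ...), acceptors, bonds (flattened
        pairs).
        """

        def grab(label: str, copy: int, required: bool) -> np.ndarray | None:
            key = f"{resname}{copy}_{label}"
            if key not in groups:
                if required:
                    raise SelectionError(f"missing index group {key!r}")
                return None
            return np.asarray(groups[key], dtype=int)

        def pairs(label: str, copy: int) -> list[tuple[int, int]]:
            flat = grab(label, copy, required=False)
            if flat is None:
                return []
            if len(flat) % 2:
                raise SelectionError(f"group {resname}{copy}_{label} has odd length")
            return [(int(flat[k]), int(flat[k + 1])) for k in range(0, len(flat), 2)]

        all_atoms, tails, heads, ohs, oonos, donors, acceptors, bonds = (
            [], [], [], [], [], [], [], [],
        )
        have_oh = have_oono = False
        for i in range(1, n_copies + 1):
            all_atoms.append(grab("all", i, True))
            tails.append(grab("tail", i, True))
            heads.append(grab("head", i, True))
            oh = grab("oh", i, False)
            oono = grab("oono", i, False)
            have_oh |= oh is not None
            have_oono |= oono is not None
            ohs.append(oh if oh is not None else np.empty(0, dtype=int))
            oonos.append(oono if oono is not None else np.empty(0, dtype=int))
            donors.append(pairs("donors", i))
            acc = grab("acceptors", i, False)
            acceptors.append(acc if acc is not None else np.empty(0, dtype=int))
            bonds.append(pairs("bonds", i))
        return cls(
            resname=resname,
            n_copies=n_copies,
            all_atoms=all_atoms,
            axis_tail=tails,
            axis_head=heads,
            oh_group=ohs if have_oh else None,
            oono_group=oonos if have_oono else None,
            donors=donors,
            acceptors=acceptors,
            bonds=bonds if any(bonds) else [],
        )

    def to_selection_groups(self) -> SelectionGroups:
        """Inverse of :meth:`from_selection_groups` (same naming scheme)."""
        out: SelectionGroups = {}
        for c in range(self.n_copies):
            i = c + 1
            out[f"{self.resname}{i}_all"] = np.asarray(self.all_atoms[c], dtype=int)
            out[f"{self.resname}{i}_tail"] = np.asarray(self.axis_tail[c], dtype=int)
            out[f"{self.resname}{i}_head"] = np.asarray(self.axis_head[c], dtype=int)
            if self.oh_group is not None and len(self.oh_group[c]):
                out[f"{self.resname}{i}_oh"] = np.asarray(self.oh_group[c], dtype=int)
            if self.oono_group is not None and len(self.oono_group[c]):
                out[f"{self.resname}{i}_oono"] = np.asarray(self.oono_group[c], dtype=int)
            if self.donors and self.donors[c]:
                out[f"{self.resname}{i}_donors"] = np.asarray(
                    [x for dh in self.donors[c] for x in dh], dtype=int
                )
            if len(self.acceptors) and len(self.acceptors[c]):
                out[f"{self.resname}{i}_acceptors"] = np.asarray(self.acceptors[c], dtype=int)
            if self.bonds and self.bonds[c]:
                out[f"{self.resname}{i}_bonds"] = np.asarray(
                    [x for ab in self.bonds[c] for x in ab], dtype=int
                )
        return out


@dataclass
class OrientationSample:
    """One (tilt angle, hydroxy depth) observation for one ligand copy."""

    frame_time: float  # ps
    copy_id: int
    theta: float  # degrees in [0, 180], vs the leaflet outward normal
    depth: float  # nm >= 0, |z(OH COM) - z(bilayer COM)| minimum-image
    leaflet: str  # "upper" | "lower"


def _copy_coords(frame: Frame, spec: LigandSpec, copy: int) -> dict[int, np.ndarray]:
    """Whole (unwrapped) coordinates of one ligand copy, keyed by global index."""
    atoms = np.asarray(spec.all_atoms[copy], dtype=int)
    if spec.bonds and spec.bonds[copy]:
        whole = make_whole(frame, atoms, spec.bonds[copy])
    else:
        whole = frame.coords[atoms]
    return {int(g): whole[i] for i, g in enumerate(atoms)}


def ligand_orientation(
    frame: Frame,
    spec: LigandSpec,
    copy: int,
    membrane: MembraneFrame,
    masses: np.ndarray,
) -> OrientationSample:
    """Tilt angle and hydroxy depth of one ligand copy in one frame.

    The axis vector is COM(axis_head) - COM(axis_tail) of the unwrapped
    copy; the leaflet is assigned by the sign of the minimum-image z
    displacement of the OH COM from the bilayer center, and θ is measured
    against that leaflet's outward normal.
    """
    if spec.oh_group is None or len(spec.oh_group[copy]) == 0:
        raise SelectionError(
            f"ligand {spec.resname!r} copy {copy} has no hydroxy (oh) group; "
            "orientation-depth analysis is undefined"
        )
    pos = _copy_coords(frame, spec, copy)
    masses = np.asarray(masses, dtype=float)

    def com(group: np.ndarray) -> np.ndarray:
        g = np.asarray(group, dtype=int)
        return center_of_mass(np.array([pos[int(i)] for i in g]), masses[g])

    com_head = com(spec.axis_head[copy])
    com_tail = com(spec.axis_tail[copy])
    com_oh = com(spec.oh_group[copy])

    axis = com_head - com_tail
    norm = float(np.linalg.norm(axis))
    if norm < 1e-9:
        raise GeometryError(f"zero-length axis vector for copy {copy}")

    dz = float(minimum_image(com_oh[2] - membrane.z_center, membrane.box[2]))
    leaflet = "upper" if dz >= 0 else "lower"
    sign = 1.0 if leaflet == "upper" else -1.0
    cos_theta = np.clip(sign * axis[2] / norm, -1.0, 1.0)
    return OrientationSample(
        frame_time=frame.time,
        copy_id=copy,
        theta=float(np.degrees(np.arccos(cos_theta))),
        depth=abs(dz),
        leaflet=leaflet,
    )


def orientation_samples(
    traj, spec: LigandSpec, lipid_group: np.ndarray
) -> list[OrientationSample]:
    """All (θ, depth) samples of a trajectory: every copy of every frame."""
    masses = traj.atoms.mass
    samples: list[OrientationSample] = []
    for fr in traj.frames:
        mem = membrane_frame(fr, lipid_group, masses)
        for c in range(spec.n_copies):
            samples.append(ligand_orientation(fr, spec, c, mem, masses))
    return samples
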