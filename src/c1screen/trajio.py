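"""Structure/trajectory I/O: multi-frame GRO files, NDX index groups, atom tables.

All coordinates are in nm, times in ps, masses in amu. Only orthorhombic
boxes are supported: the downstream membrane analysis assumes axis-aligned
periodicity, so triclinic input is rejected rather than silently skewed.
Velocities present in GRO frames are parsed and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import guess_element, mass_of, vdw_radius_of
from .errors import (
    GroParseError,
    GroWriteError,
    SelectionError,
    UnsupportedFormatError,
)

__all__ = [
    "AtomTable",
    "Frame",
    "Trajectory",
    "SelectionGroups",
    "read_gro",
    "write_gro",
    "read_index_groups",
    "write_index_groups",
]


@dataclass
class AtomTable:
    """Per-atom static attributes shared by every frame of a trajectory."""

    name: np.ndarray  # str
    resname: np.ndarray  # str
    resid: np.ndarray  # int
    mass: np.ndarray  # amu
    vdw_radius: np.ndarray  # nm
    element: np.ndarray  # str

    def __post_init__(self) -> None:
        n = len(self.name)
        for f in ("resname", "resid", "mass", "vdw_radius", "element"):
            if len(getattr(self, f)) != n:
                raise SelectionError(f"atom table column {f!r} has wrong length")
        if n and (np.asarray(self.mass) <= 0).any():
            raise SelectionError("atom masses must be positive")
        if n and (np.asarray(self.vdw_radius) <= 0).any():
            raise SelectionError("vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @classmethod
    def from_names(
        cls,
        names,
        resnames,
        resids,
        overrides: dict[str, tuple[float, float]] | None = None,
    ) -> "AtomTable":
        """Build a table inferring element/mass/radius from atom names.

        ``overrides`` maps atom name -> (mass, vdw_radius); names present
        there skip element inference (element recorded as the name itself).
        """
        overrides = overrides or {}
        elements, masses, radii = [], [], []
        for nm in names:
            if nm in overrides:
                m, r = overrides[nm]
                elements.append(nm)
                masses.append(m)
                radii.append(r)
            else:
                el = guess_element(nm)
                elements.append(el)
                masses.append(mass_of(el))
                radii.append(vdw_radius_of(el))
        return cls(
            name=np.asarray(list(names), dtype=object),
            resname=np.asarray(list(resnames), dtype=object),
            resid=np.asarray(list(resids), dtype=int),
            mass=np.asarray(masses, dtype=float),
            vdw_radius=np.asarray(radii, dtype=float),
            element=np.asarray(elements, dtype=object),
        )


@dataclass
class Frame:
    """One time point: orthorhombic box edges (nm) and per-atom coordinates (nm)."""

    time: float  # ps
    box: np.ndarray  # (3,) edge lengths, nm
    coords: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,) or (self.box <= 0).any():
            raise UnsupportedFormatError("box must be three positive edge lengths")
        if not np.isfinite(self.coords).all() or not np.isfinite(self.box).all():
            raise GroParseError("non-finite coordinates or box")


@dataclass
class Trajectory:
    """An ordered frame sequence over one atom table."""

    atoms: AtomTable
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.atoms.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.coords.shape != (n, 3):
                raise GroParseError(
                    f"frame {i + 1} has {fr.coords.shape[0]} atoms, table has {n}"
                )
        times = self.times
        if len(times) > 1 and not (np.diff(times) > 0).all():
            raise GroParseError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return self.atoms.n_atoms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([fr.time for fr in self.frames], dtype=float)

    def __iter__(self):
        return iter(self.frames)


# A SelectionGroups is a plain ordered mapping: group label -> 0-based index array.
SelectionGroups = dict[str, np.ndarray]


def _parse_box_line(line: str, frame_no: int) -> np.ndarray:
    parts = line.split()
    try:
        vals = [float(p) for p in parts]
    except ValueError:
        raise GroParseError(f"frame {frame_no}: unreadable box line {line!r}") from None
    if len(vals) == 3:
        return np.asarray(vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise UnsupportedFormatError(
                f"frame {frame_no}: triclinic box (nonzero off-diagonal terms) "
                "is not supported"
            )
        return np.asarray(vals[:3])
    raise GroParseError(f"frame {frame_no}: box line has {len(vals)} fields")


def _frame_time(title: str, frame_no: int) -> float:
    # GRO convention: "... t= <time>" in the title line; fall back to the
    # 0-based frame index so multi-frame files without times stay ordered.
    if "t=" in title:
        tail = title.rsplit("t=", 1)[1].split()
        if tail:
            try:
                return float(tail[0])
            except ValueError:
                pass
    return float(frame_no - 1)


def read_gro(
    path,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> Trajectory:
    """Read a (possibly multi-frame) GRO file into a Trajectory.

    Coordinates are taken at the format's 3-decimal fixed precision;
    velocity columns, if present, are ignored. Masses and radii come from
    the element lookup keyed on atom name (see :mod:`c1screen.elements`),
    overridable per atom name.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    frames: list[Frame] = []
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    pos = 0
    frame_no = 0
    first = True
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break  # trailing blank line
        frame_no += 1
        title = lines[pos]
        if pos + 1 >= len(lines):
            raise GroParseError(f"frame {frame_no}: missing atom-count line")
        try:
            n_atoms = int(lines[pos + 1].strip())
        except ValueError:
            raise GroParseError(
                f"frame {frame_no}: atom-count line {lines[pos + 1]!r} is not an integer"
            ) from None
        body_start = pos + 2
        body_end = body_start + n_atoms
        if body_end > len(lines) - 1:  # need a box line after the body
            raise GroParseError(
                f"frame {frame_no}: declares {n_atoms} atoms but the file ends "
                f"after {max(0, len(lines) - body_start)} atom lines (line {len(lines)})"
            )
        coords = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            line = lines[body_start + i]
            if len(line) < 44:
                raise GroParseError(
                    f"frame {frame_no}: atom line {body_start + i + 1} too short: {line!r}"
                )
            try:
                coords[i, 0] = float(line[20:28])
                coords[i, 1] = float(line[28:36])
                coords[i, 2] = float(line[36:44])
            except ValueError:
                raise GroParseError(
                    f"frame {frame_no}: unreadable coordinates on line {body_start + i + 1}"
                ) from None
            if first:
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
        box = _parse_box_line(lines[body_end], frame_no)
        frames.append(Frame(time=_frame_time(title, frame_no), box=box, coords=coords))
        if first:
            atoms = AtomTable.from_names(names, resnames, resids, overrides)
            first = False
        elif n_atoms != atoms.n_atoms:
            raise GroParseError(
                f"frame {frame_no}: atom count {n_atoms} differs from frame 1 "
                f"({atoms.n_atoms})"
            )
        pos = body_end + 1

    if first:
        raise GroParseError("empty GRO file: no frames found")
    return Trajectory(atoms=atoms, frames=frames)


def write_gro(traj: Trajectory, path) -> None:
    """Write a Trajectory as concatenated fixed-column GRO frame blocks.

    Coordinates are rounded to 3 decimals (the format's precision); values
    that do not fit the 8-character fixed column raise ``GroWriteError``.
    """
    if traj.n_frames == 0:
        raise GroWriteError("refusing to write an empty trajectory")
    at = traj.atoms
    with open(path, "w") as fh:
        for fr in traj.frames:
            if (np.abs(fr.coords) >= 10000).any() or (fr.box >= 100000).any():
                raise GroWriteError(
                    "coordinate or box magnitude exceeds GRO fixed-column width"
                )
            fh.write(f"c1screen frame t= {fr.time:.3f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for i in range(traj.n_atoms):
                fh.write(
                    f"{int(at.resid[i]) % 100000:5d}{str(at.resname[i])[:5]:<5s}"
                    f"{str(at.name[i])[:5]:>5s}{(i + 1) % 100000:5d}"
                    f"{fr.coords[i, 0]:8.3f}{fr.coords[i, 1]:8.3f}{fr.coords[i, 2]:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def read_index_groups(path, atoms: AtomTable) -> SelectionGroups:
    """Read NDX-style bracketed index groups, converting to 0-based indices.

    Group order and within-group order are preserved. Out-of-range indices
    and duplicate group names raise ``SelectionError``.
    """
    groups: SelectionGroups = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                name = line.strip("[] \t")
                if name in groups:
                    raise SelectionError(f"duplicate group name {name!r} (line {lineno})")
                groups[name] = []  # type: ignore[assignment]
                current = name
                continue
            if current is None:
                raise SelectionError(f"index data before any group header (line {lineno})")
            for tok in line.split():
                try:
                    idx1 = int(tok)
                except ValueError:
                    raise SelectionError(
                        f"group {current!r}: non-integer index {tok!r} (line {lineno})"
                    ) from None
                if not (1 <= idx1 <= atoms.n_atoms):
                    raise SelectionError(
                        f"group {current!r}: index {idx1} out of range "
                        f"(1..{atoms.n_atoms})"
                    )
                groups[current].append(idx1 - 1)  # type: ignore[attr-defined]
    out: SelectionGroups = {}
    for name, idx in groups.items():
        arr = np.asarray(idx, dtype=int)
        # pair-list groups (bonds, donor D-H pairs) legitimately repeat atoms
        if not name.endswith(("_bonds", "_donors")) and len(np.unique(arr)) != len(arr):
            raise SelectionError(f"group {name!r} contains duplicate indices")
        out[name] = arr
    return out


def write_index_groups(groups: SelectionGroups, path) -> None:
    """Write selection groups in the NDX dialect (1-based, 15 indices/line)."""
    with open(path, "w") as fh:
        for name, idx in groups.items():
            fh.write(f"[ {name} ]\n")
            idx1 = [str(int(i) + 1) for i in np.asarray(idx).ravel()]
            for start in range(0, len(idx1), 15):
                fh.write(" ".join(idx1[start : start + 15]) + "\n")
            if not len(idx1):
                fh.write("\n")
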