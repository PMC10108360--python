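"""Dot-surface (Shrake-Rupley) solvent-accessible surface area.

Each atom is assigned a quasi-uniform Fibonacci-spiral lattice of points on
its probe-expanded sphere of radius r_vdw + probe; the accessible area is
4π(r+probe)² times the fraction of points not inside any occluder's
expanded sphere. The spiral lattice is deterministic, so areas are exactly
reproducible without a seed. Distances use the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockAverage, block_average
from .errors import ConfigError, SelectionError
from .geometry import LigandSpec, minimum_image
from .trajio import Frame, Trajectory

__all__ = ["SasaSettings", "fibonacci_sphere", "shrake_rupley", "group_sasa_block_stats"]


@dataclass
class SasaSettings:
    probe_radius: float = 0.14  # nm (water probe)
    n_dots: int = 960  # points per atomic sphere
    radii_source: str = "bondi"

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ConfigError("probe radius must be >= 0")
        if self.n_dots < 24:
            raise ConfigError("need at least 24 dots per sphere")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden-angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    frame: Frame,
    atoms: np.ndarray,
    occluders: np.ndarray,
    radii: np.ndarray,
    settings: SasaSettings | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible area (nm²) of ``atoms``.

    ``occluders`` may be any selection (typically every atom in the
    system); an atom never occludes itself. ``radii`` is the full per-atom
    vdW radius array (nm).
    """
    settings = settings or SasaSettings()
    atoms = np.asarray(atoms, dtype=int)
    occluders = np.asarray(occluders, dtype=int)
    radii = np.asarray(radii, dtype=float)
    for sel in (atoms, occluders):
        if len(sel) and not np.isfinite(radii[sel]).all():
            bad = sel[~np.isfinite(radii[sel])][0]
            raise SelectionError(f"missing vdW radius for atom {bad}")

    dots = fibonacci_sphere(settings.n_dots)
    coords, box = frame.coords, frame.box
    p = settings.probe_radius
    occ_r = radii[occluders] + p
    max_occ = occ_r.max() if len(occluders) else 0.0

    areas = np.empty(len(atoms))
    for k, i in enumerate(atoms):
        big_r = radii[i] + p
        full = 4.0 * np.pi * big_r * big_r
        if not len(occluders):
            areas[k] = full
            continue
        # prefilter occluders whose expanded sphere can reach this atom's surface
        disp = minimum_image(coords[occluders] - coords[i], box)
        dist = np.linalg.norm(disp, axis=1)
        near = (dist < big_r + max_occ) & (occluders != i)
        if not near.any():
            areas[k] = full
            continue
        near_disp = disp[near]
        near_r2 = occ_r[near] ** 2
        surf = dots * big_r  # dot positions relative to the atom center
        # dot j occluded iff |surf_j - near_disp_m| < occ_r_m for some m
        d2 = ((surf[:, None, :] - near_disp[None, :, :]) ** 2).sum(axis=2)
        free = ~(d2 < near_r2[None, :]).any(axis=1)
        areas[k] = full * free.mean()
    return areas


def group_sasa_block_stats(
    traj: Trajectory,
    spec: LigandSpec,
    group: str,
    settings: SasaSettings | None = None,
    n_blocks: int = 5,
    include_other_copies: bool = True,
) -> BlockAverage:
    """SASA (nm²) of a ligand functional group per molecule, block-averaged.

    Per frame: the summed area of the group's atoms with every other system
    atom as an occluder (optionally excluding the other ligand copies),
    averaged over copies; then the block statistics over contiguous
    equal-duration blocks.
    """
    settings = settings or SasaSettings()
    if group == "oh":
        groups = spec.oh_group
    elif group == "oono":
        groups = spec.oono_group
    else:
        raise ConfigError(f"unknown ligand group {group!r} (expected 'oh' or 'oono')")
    if groups is None or any(len(g) == 0 for g in groups):
        raise SelectionError(f"ligand {spec.resname!r} lacks the {group!r} group")

    radii = traj.atoms.vdw_radius
    all_idx = np.arange(traj.n_atoms)
    series = []
    for fr in traj.frames:
        per_copy = []
        for c in range(spec.n_copies):
            occ = all_idx
            if not include_other_copies:
                others = np.concatenate(
                    [spec.all_atoms[o] for o in range(spec.n_copies) if o != c]
                ) if spec.n_copies > 1 else np.empty(0, dtype=int)
                occ = np.setdiff1d(all_idx, others)
            per_copy.append(
                shrake_rupley(fr, np.asarray(groups[c], dtype=int), occ, radii, settings).sum()
            )
        series.append(float(np.mean(per_copy)))
    return block_average(series, traj.times, n_blocks)
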