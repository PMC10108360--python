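"""Partial mass-density profiles along the membrane normal and the
lipid-water interface position.

Each frame is recentered so the lipid-group COM sits at z = 0 (removing
slow bilayer drift), atom masses are accumulated into signed-z bins by
minimum image, and the histogram is converted to kg·m⁻³ using the lateral
box area times the bin width. Mass density (rather than number density) is
used so whole-molecule and small-group profiles share one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ConfigError, GeometryError
from .geometry import minimum_image, pbc_com_z
from .trajio import Trajectory

__all__ = ["DensityProfile", "partial_density", "locate_interface", "AMU_PER_NM3_TO_KG_M3"]

# 1 amu / nm^3 = 1.66053906660e-27 kg / 1e-27 m^3
AMU_PER_NM3_TO_KG_M3 = 1.66053906660


@dataclass
class DensityProfile:
    """Frame-averaged mass density vs signed z (nm, relative to bilayer COM)."""

    bin_centers: np.ndarray  # nm, signed
    density: np.ndarray  # kg m^-3
    label: str
    n_frames: int
    bin_width: float  # nm
    lateral_area: float  # nm^2, frame-averaged

    def mass_integral(self) -> float:
        """Σ density · A · Δz converted back to amu — equals the group mass."""
        kg = float(self.density.sum()) * self.lateral_area * self.bin_width
        return kg / AMU_PER_NM3_TO_KG_M3

    def folded(self) -> "DensityProfile":
        """|z| view: densities at ±z averaged (plotting option)."""
        pos = self.bin_centers > 0
        neg = self.bin_centers < 0
        centers = self.bin_centers[pos]
        dens = 0.5 * (self.density[pos] + self.density[neg][::-1])
        return DensityProfile(
            bin_centers=centers,
            density=dens,
            label=self.label + " (folded)",
            n_frames=self.n_frames,
            bin_width=self.bin_width,
            lateral_area=self.lateral_area,
        )


def partial_density(
    traj: Trajectory,
    group: np.ndarray,
    bin_width: float,
    reference: np.ndarray,
    label: str = "",
) -> DensityProfile:
    """Partial mass-density profile of ``group`` along z.

    ``reference`` (the lipid group) defines the per-frame bilayer COM used
    to recenter every frame at z = 0. The bin grid spans the smallest whole
    number of bins covering the box height, so every minimum-image
    displacement lands in a bin and group mass is conserved exactly.
    """
    if bin_width <= 0:
        raise ConfigError("bin width must be positive")
    reference = np.asarray(reference, dtype=int)
    if reference.size == 0:
        raise GeometryError("empty reference (lipid) group")
    group = np.asarray(group, dtype=int)
    if traj.n_frames == 0:
        raise AnalysisError("empty trajectory")
    box_z0 = traj.frames[0].box[2]
    if bin_width > box_z0:
        raise ConfigError("bin width exceeds the box height")

    n_bins = int(np.ceil(box_z0 / bin_width - 1e-9))
    half = n_bins * bin_width / 2.0
    edges = np.linspace(-half, half, n_bins + 1)

    masses = traj.atoms.mass
    ref_m = masses[reference]
    grp_m = masses[group] if group.size else np.empty(0)
    acc = np.zeros(n_bins)
    area_sum = 0.0
    for fr in traj.frames:
        z_c = pbc_com_z(fr.coords[reference, 2], ref_m, fr.box[2])
        area_sum += float(fr.box[0] * fr.box[1])
        if group.size == 0:
            continue
        dz = minimum_image(fr.coords[group, 2] - z_c, fr.box[2])
        hist, _ = np.histogram(dz, bins=edges, weights=grp_m)
        acc += hist
    area = area_sum / traj.n_frames
    density = acc / traj.n_frames / (area * bin_width) * AMU_PER_NM3_TO_KG_M3
    return DensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        label=label,
        n_frames=traj.n_frames,
        bin_width=bin_width,
        lateral_area=area,
    )


def _outermost_crossing(z: np.ndarray, diff: np.ndarray) -> float | None:
    """Outermost genuine sign change of ``diff``, linearly interpolated.

    Zero plateaus between opposite-signed values are interpolated across;
    profiles that never change sign (e.g. no water present) yield ``None``.
    """
    nz = np.flatnonzero(diff)
    crossings = []
    for k in range(len(nz) - 1):
        i, j = nz[k], nz[k + 1]
        a, b = diff[i], diff[j]
        if a * b < 0:
            crossings.append(float(z[i] - a * (z[j] - z[i]) / (b - a)))
    if not crossings:
        return None
    return max(crossings, key=abs)


def locate_interface(water: DensityProfile, lipid: DensityProfile) -> dict[str, float]:
    """Lipid-water interface |z| per leaflet.

    The interface is where linear interpolation of (water − lipid) density
    changes sign; the outermost crossing in each half-space is taken.
    Returns ``{"lower": |z|, "upper": |z|}`` in nm.
    """
    if len(water.bin_centers) != len(lipid.bin_centers) or not np.allclose(
        water.bin_centers, lipid.bin_centers
    ):
        raise ConfigError("profiles must share one binning")
    z = water.bin_centers
    diff = water.density - lipid.density
    out: dict[str, float] = {}
    for name, mask in (("lower", z < 0), ("upper", z > 0)):
        cross = _outermost_crossing(z[mask], diff[mask])
        if cross is None:
            raise AnalysisError(f"no lipid-water interface crossing in the {name} half-space")
        out[name] = abs(cross)
    return out
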