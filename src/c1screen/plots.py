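"""Rendering of orientation heat maps and density profiles (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .density import DensityProfile
from .orientation import HeatMap2D

__all__ = ["plot_heatmap", "plot_density_profiles"]


def plot_heatmap(hmap: HeatMap2D, path, title: str = "") -> None:
    """Render the (θ, depth) population map as a probability heat map."""
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        hmap.theta_edges, hmap.depth_edges, hmap.probability().T, cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label="population fraction")
    ax.set_xlabel("tilt angle θ (degrees)")
    ax.set_ylabel("hydroxy depth from bilayer center (nm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_density_profiles(
    profiles: list[DensityProfile], path, interface: dict[str, float] | None = None
) -> None:
    """Overlay partial density profiles; optional lipid-water interface lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for prof in profiles:
        ax.plot(prof.bin_centers, prof.density, label=prof.label or None)
    if interface:
        for side, z in interface.items():
            x = z if side == "upper" else -z
            ax.axvline(x, color="tab:blue", linestyle=":", linewidth=1)
    ax.set_xlabel("z from bilayer center (nm)")
    ax.set_ylabel("partial mass density (kg m$^{-3}$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
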