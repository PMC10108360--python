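"""Orientation-depth population heat maps and the correct/incorrect classifier.

The 2D histogram of (tilt angle θ, hydroxy depth) samples is the screening
readout: DAG-mimetic candidates that insert like the positive control show
a dominant population at small θ (axis pointing out of the membrane) and a
hydroxy group near the lipid headgroups (~1.6 nm from the bilayer center),
while internally hydrogen-bonded negative controls flip (θ well above 90°)
and sink toward the bilayer center (~1 nm).

Classification uses the *mode* cell of the raw-count map — the reasoning is
about the main population, not the mean — and reports the weight of the
opposing-orientation population separately instead of penalising it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ConfigError
from .geometry import OrientationSample

__all__ = [
    "HeatMap2D",
    "OrientationVerdict",
    "ClassifierThresholds",
    "accumulate_heatmap",
    "find_mode",
    "classify_orientation",
]

DEFAULT_THETA_BIN = 5.0  # degrees
DEFAULT_DEPTH_BIN = 0.05  # nm


@dataclass
class HeatMap2D:
    """Raw-count population map over (θ, depth) bins.

    Bins are half-open [lo, hi) with the last bin closed (numpy histogram
    convention); counts are kept unnormalised so that Σcounts == n_samples
    exactly.
    """

    theta_edges: np.ndarray  # degrees, uniform over [0, 180]
    depth_edges: np.ndarray  # nm
    counts: np.ndarray  # (n_theta_bins, n_depth_bins) int
    n_samples: int

    def __post_init__(self) -> None:
        if (np.diff(self.theta_edges) <= 0).any() or (np.diff(self.depth_edges) <= 0).any():
            raise ConfigError("histogram edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_samples:
            raise AnalysisError("count conservation violated: sum(counts) != n_samples")

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    def probability(self) -> np.ndarray:
        """Counts normalised to a probability mass function (plotting aid)."""
        if self.n_samples == 0:
            return self.counts.astype(float)
        return self.counts / self.n_samples


def accumulate_heatmap(
    samples,
    theta_bin: float = DEFAULT_THETA_BIN,
    depth_bin: float = DEFAULT_DEPTH_BIN,
    depth_max: float | None = None,
) -> HeatMap2D:
    """Bin (θ, depth) samples into a population heat map.

    θ bins tile [0, 180] uniformly. Depth bins tile [0, depth_max]; if
    ``depth_max`` is not given it is the smallest bin multiple covering the
    largest observed depth. An empty stream yields an empty (all-zero) map.
    """
    if theta_bin <= 0 or depth_bin <= 0:
        raise ConfigError("bin widths must be positive")
    samples = list(samples)
    thetas = np.array([s.theta for s in samples], dtype=float)
    depths = np.array([s.depth for s in samples], dtype=float)
    if len(samples):
        if (thetas < 0).any() or (thetas > 180).any():
            raise AnalysisError("tilt angles outside [0, 180] degrees")
        if (depths < 0).any():
            raise AnalysisError("negative depths")

    n_theta = int(np.ceil(180.0 / theta_bin))
    theta_edges = np.arange(n_theta + 1) * theta_bin
    if depth_max is None:
        top = depths.max() if len(samples) else depth_bin
        depth_max = max(depth_bin, float(np.ceil(top / depth_bin - 1e-9) * depth_bin))
    if len(samples) and (depths > depth_max + 1e-12).any():
        raise AnalysisError(f"depths exceed depth_max = {depth_max} nm")
    n_depth = int(round(depth_max / depth_bin))
    depth_edges = np.arange(n_depth + 1) * depth_bin

    counts, _, _ = np.histogram2d(thetas, depths, bins=[theta_edges, depth_edges])
    return HeatMap2D(
        theta_edges=theta_edges,
        depth_edges=depth_edges,
        counts=counts.astype(int),
        n_samples=len(samples),
    )


def find_mode(hmap: HeatMap2D) -> tuple[float, float]:
    """Center (θ, depth) of the maximal-count cell.

    Ties are broken deterministically toward the smallest θ, then the
    smallest depth.
    """
    if hmap.n_samples == 0:
        raise AnalysisError("cannot locate the mode of an empty heat map")
    best = int(np.argmax(hmap.counts))  # row-major argmax = lexicographic (θ, depth) tie-break
    ti, di = np.unravel_index(best, hmap.counts.shape)
    return float(hmap.theta_centers[ti]), float(hmap.depth_centers[di])


@dataclass
class ClassifierThresholds:
    """Mode-cell thresholds separating the reference populations.

    Defaults are calibrated to sit between the positive-control population
    (θ ≲ 50°, depth ~1.6 nm) and the negative-control population
    (θ ≳ 130°, depth ~1 nm), with a deliberate ambiguous gap between them.
    """

    theta_ok: float = 60.0  # degrees: correct requires mode θ <= theta_ok
    depth_ok: float = 1.4  # nm: correct requires mode depth >= depth_ok
    theta_bad: float = 120.0  # degrees: incorrect requires mode θ >= theta_bad
    depth_bad: float = 1.2  # nm: incorrect requires mode depth <= depth_bad

    def __post_init__(self) -> None:
        if self.theta_ok >= self.theta_bad:
            raise ConfigError("thresholds non-monotone: theta_ok must be < theta_bad")
        if self.depth_bad > self.depth_ok:
            raise ConfigError("thresholds non-monotone: depth_bad must be <= depth_ok")


@dataclass
class OrientationVerdict:
    mode_theta: float  # degrees
    mode_depth: float  # nm
    label: str  # "correct" | "incorrect" | "ambiguous"
    secondary_population_fraction: float  # weight of θ on the far side of 90°


def classify_orientation(
    hmap: HeatMap2D, thresholds: ClassifierThresholds | None = None
) -> OrientationVerdict:
    """Label a candidate from its heat-map mode.

    correct    — mode θ <= theta_ok and mode depth >= depth_ok
    incorrect  — mode θ >= theta_bad and mode depth <= depth_bad
    ambiguous  — anything else.

    The secondary population fraction is the sample weight with θ on the
    opposite side of 90° from the mode (flipped-orientation population).
    """
    thresholds = thresholds or ClassifierThresholds()
    mode_theta, mode_depth = find_mode(hmap)
    if mode_theta <= thresholds.theta_ok and mode_depth >= thresholds.depth_ok:
        label = "correct"
    elif mode_theta >= thresholds.theta_bad and mode_depth <= thresholds.depth_bad:
        label = "incorrect"
    else:
        label = "ambiguous"

    centers = hmap.theta_centers
    opposite = centers > 90.0 if mode_theta <= 90.0 else centers < 90.0
    secondary = float(hmap.counts[opposite].sum() / hmap.n_samples)
    return OrientationVerdict(
        mode_theta=mode_theta,
        mode_depth=mode_depth,
        label=label,
        secondary_population_fraction=secondary,
    )
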