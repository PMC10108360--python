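"""Transient ligand-cluster detection.

Two ligand copies are adjacent when their minimum-image minimum
inter-atomic distance is within a cutoff (single linkage); clusters are the
connected components of that adjacency. The default cutoff of 0.4 nm is a
conventional contact distance and is a configuration key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, SelectionError
from .geometry import LigandSpec, minimum_image
from .trajio import Frame, Trajectory

__all__ = ["ClusterState", "ligand_clusters", "cluster_timeseries"]

DEFAULT_CLUSTER_CUTOFF = 0.4  # nm


@dataclass
class ClusterState:
    """Partition of the ligand copies into clusters at one frame."""

    frame_time: float
    clusters: list[tuple[int, ...]]  # sorted copy-id tuples, sorted by first member
    largest_cluster_size: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _min_copy_distance(frame: Frame, a: np.ndarray, b: np.ndarray) -> float:
    disp = minimum_image(
        frame.coords[np.asarray(b, dtype=int)][None, :, :]
        - frame.coords[np.asarray(a, dtype=int)][:, None, :],
        frame.box,
    )
    return float(np.sqrt((disp**2).sum(axis=2)).min())


def ligand_clusters(
    frame: Frame, spec: LigandSpec, cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> ClusterState:
    """Single-linkage clusters of the ligand copies in one frame."""
    if cutoff <= 0:
        raise ConfigError("cluster cutoff must be positive")
    n = spec.n_copies
    if n == 0:
        raise SelectionError("no ligand copies")
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if _min_copy_distance(frame, spec.all_atoms[i], spec.all_atoms[j]) <= cutoff:
                rows += [i, j]
                cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = [tuple(sorted(np.flatnonzero(labels == c))) for c in range(n_comp)]
    clusters.sort(key=lambda t: t[0])
    return ClusterState(
        frame_time=frame.time,
        clusters=clusters,
        largest_cluster_size=max(len(c) for c in clusters),
    )


def cluster_timeseries(
    traj: Trajectory, spec: LigandSpec, cutoff: float = DEFAULT_CLUSTER_CUTOFF
):
    """Per-frame cluster states plus a summary.

    Returns ``(states, summary)`` where summary holds the fraction of
    frames with any cluster of size >= 2 and the mean largest cluster size.
    """
    states = [ligand_clusters(fr, spec, cutoff) for fr in traj.frames]
    largest = np.asarray([s.largest_cluster_size for s in states], dtype=float)
    summary = {
        "clustered_frame_fraction": float((largest >= 2).mean()) if len(states) else 0.0,
        "mean_largest_cluster_size": float(largest.mean()) if len(states) else 0.0,
        "cutoff_nm": cutoff,
        "n_frames": len(states),
    }
    return states, summary
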