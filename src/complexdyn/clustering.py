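"""Snapshot coarsening, threshold clustering on the 2D-RMSD map, and
representative-structure selection.

The trajectory is first coarsened into frames of consecutive snapshots (a
2 us / 1001-snapshot run in blocks of ten yields 101 frames: 100 full blocks
plus a final singleton). Frames whose pairwise backbone RMSD falls below the
cutoff are merged transitively into clusters, and each cluster's
representative is the member with the smallest mean RMSD to the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import BlockTooLargeError
from .structure import Trajectory
from .superpose import RMSDMatrix, kabsch

__all__ = ["FrameSet", "ClusterAssignment", "coarsen", "cluster_threshold", "representative"]


@dataclass
class FrameSet:
    """Coarse frames: consecutive snapshot blocks with mean structures."""

    spans: list[tuple[int, int]]  # inclusive snapshot index ranges
    mean_coords: np.ndarray  # (n_frames, n_atoms, 3)
    source: Trajectory

    @property
    def n_frames(self) -> int:
        return len(self.spans)

    def times_ns(self) -> np.ndarray:
        """Midpoint time of each frame's snapshot span."""
        t = self.source.times_ns
        return np.asarray([(t[a] + t[b]) / 2 for a, b in self.spans])

    def span_times_ns(self) -> list[tuple[float, float]]:
        t = self.source.times_ns
        return [(float(t[a]), float(t[b])) for a, b in self.spans]


def coarsen(traj: Trajectory, block: int) -> FrameSet:
    """Divide snapshots into consecutive blocks and average each block.

    Every full block holds ``block`` snapshots; a remainder forms one final
    smaller frame. Block members are superposed onto the block's first
    snapshot (all atoms) before averaging, so the mean is not blurred by
    rigid drift within the block.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    n = traj.n_frames
    if block > n:
        raise BlockTooLargeError(f"block {block} exceeds snapshot count {n}")
    spans: list[tuple[int, int]] = []
    start = 0
    while start < n:
        end = min(start + block, n)
        spans.append((start, end - 1))
        start = end
    means = np.empty((len(spans), len(traj.topology), 3))
    for fi, (a, b) in enumerate(spans):
        ref = traj.frames[a]
        acc = np.zeros_like(ref)
        for s in range(a, b + 1):
            if s == a or block == 1:
                acc += traj.frames[s]
            else:
                res = kabsch(traj.frames[s], ref)
                acc += traj.frames[s] @ res.rotation.T + res.translation
        means[fi] = acc / (b - a + 1)
    return FrameSet(spans=spans, mean_coords=means, source=traj)


@dataclass
class ClusterAssignment:
    """Frame -> cluster map with largest cluster and representatives."""

    labels: np.ndarray  # per-frame cluster id
    clusters: dict[int, list[int]]  # id -> member frame indices
    largest: int
    representative: dict[int, int]  # id -> representative frame index

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def representative(matrix: RMSDMatrix, members) -> int:
    """Member frame with minimal mean RMSD to the other members.

    Singleton clusters return their only frame; exact ties go to the
    earliest frame (argmin on the ordered member list).
    """
    members = list(members)
    if not members:
        raise ValueError("members must be non-empty")
    if len(members) == 1:
        return members[0]
    sub = matrix.values[np.ix_(members, members)]
    mean_to_others = sub.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(mean_to_others))]


def cluster_threshold(matrix: RMSDMatrix, cutoff: float) -> ClusterAssignment:
    """Single-linkage threshold clustering of the 2D-RMSD matrix.

    Two frames belong together when their RMSD is strictly below ``cutoff``;
    clusters are the connected components of that graph (the transitive
    closure of the pairwise rule). Cluster ids are assigned in order of each
    cluster's earliest member frame, so the labeling is deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adj = csr_matrix(matrix.values < cutoff)
    _, raw = connected_components(adj, directed=False)
    # relabel by earliest member
    order: dict[int, int] = {}
    for frame, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
    labels = np.asarray([order[l] for l in raw], dtype=int)
    clusters: dict[int, list[int]] = {}
    for frame, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(frame)
    largest = max(clusters, key=lambda c: (len(clusters[c]), -c))
    reps = {c: representative(matrix, m) for c, m in clusters.items()}
    return ClusterAssignment(
        labels=labels, clusters=clusters, largest=largest, representative=reps
    )
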