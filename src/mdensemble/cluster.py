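"""Pairwise-RMSD frame clustering and representative-structure extraction.

Frames are clustered with the deterministic neighbor-count (GROMOS-style)
procedure: the frame with the most neighbors within the RMSD cutoff seeds a
cluster, the cluster is removed, and the scan repeats.  Ties in neighborhood
size are broken by the lower frame index.  The "most representative
structure" of a state is the medoid (minimum summed RMSD to its members) of
the most populated cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError
from .fit import kabsch_superpose
from .selections import AtomSelection
from .structure_io import StructureModel, Trajectory


@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id per frame (in stride order)
    frame_indices: np.ndarray   # original frame index per matrix row
    populations: dict           # cluster id -> size
    representatives: dict       # cluster id -> frame index (medoid)
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    @property
    def top_cluster(self) -> int:
        return min(self.populations, key=lambda c: (-self.populations[c], c))


def pairwise_rmsd(traj: Trajectory, selection: AtomSelection,
                  stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of post-superposition RMSDs between frames.

    Returns ``(matrix, frame_indices)`` where row/col ``a`` corresponds to
    original frame ``frame_indices[a]`` (every ``stride``-th frame).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = np.arange(0, traj.n_frames, stride)
    coords = traj.coords[frames][:, selection.indices, :]
    m = len(frames)
    mat = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            mat[a, b] = mat[b, a] = kabsch_superpose(coords[a], coords[b]).rmsd
    return mat, frames


def cluster_frames(matrix: np.ndarray, cutoff: float,
                   frame_indices: np.ndarray | None = None) -> ClusterResult:
    """GROMOS-style neighbor-count clustering of a frame-distance matrix."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8) or np.abs(np.diag(mat)).max() > 1e-8:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    m = mat.shape[0]
    frames = np.arange(m) if frame_indices is None else np.asarray(frame_indices)
    remaining = np.ones(m, dtype=bool)
    labels = np.full(m, -1, dtype=int)
    neighbors = mat <= cutoff
    cid = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[seed] & remaining)
        labels[members] = cid
        remaining[members] = False
        cid += 1

    populations = {c: int(np.sum(labels == c)) for c in range(cid)}
    representatives = {}
    for c in range(cid):
        members = np.flatnonzero(labels == c)
        sums = mat[np.ix_(members, members)].sum(axis=1)
        representatives[c] = int(frames[members[int(np.argmin(sums))]])
    return ClusterResult(labels=labels, frame_indices=frames,
                         populations=populations,
                         representatives=representatives, cutoff=cutoff)


def representative_structure(traj: Trajectory, result: ClusterResult,
                             cluster: int | None = None) -> StructureModel:
    """Topology dressed with the medoid frame of a cluster (default: largest)."""
    c = result.top_cluster if cluster is None else cluster
    return traj.topology.with_coordinates(traj.coords[result.representatives[c]])


def compare_representatives(rep_a: StructureModel, rep_b: StructureModel,
                            selection_a: AtomSelection,
                            selection_b: AtomSelection | None = None) -> float:
    """Superposed RMSD between two representative structures.

    The selections must map residue-to-residue between the models (same
    length, same residue number and atom name per position); unmatched
    positions are an error listing the offending residues.
    """
    sb = selection_b if selection_b is not None else selection_a
    ia, ib = selection_a.indices, sb.indices
    if len(ia) != len(ib):
        raise SelectionError(
            f"selections differ in length: {len(ia)} vs {len(ib)}")
    mism = [
        f"{rep_a.resid[a]}{rep_a.name[a]} != {rep_b.resid[b]}{rep_b.name[b]}"
        for a, b in zip(ia, ib)
        if rep_a.resid[a] != rep_b.resid[b] or rep_a.name[a] != rep_b.name[b]
    ]
    if mism:
        raise SelectionError(f"unmatched residues between models: {mism[:10]}")
    return kabsch_superpose(rep_a.coord[ia], rep_b.coord[ib]).rmsd
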