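"""Essential dynamics: Cα covariance PCA, projections, free-energy landscapes.

Frames are first rigid-body fitted to a shared reference so overall
translation/rotation does not leak into the covariance.  The covariance of
the 3N fitted Cartesian coordinates is diagonalized with a symmetric
eigensolver; eigenvector signs are fixed by making each vector's
largest-magnitude component positive so projections are reproducible.

The 2-D landscape over (PC1, PC2) is the Boltzmann inversion
``ΔG = -k_B T ln(ρ/ρ_max)`` with the occupied minimum pinned at exactly 0
and empty bins carrying NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .fit import superpose_frames
from .selections import AtomSelection
from .structure_io import StructureModel, Trajectory


@dataclass
class PCModel:
    mean: np.ndarray              # (n, 3) mean fitted selection coordinates
    eigenvalues: np.ndarray       # (3n,), Å², descending
    eigenvectors: np.ndarray      # (3n, 3n), columns, orthonormal
    variance_fractions: np.ndarray
    reference_coords: np.ndarray  # (n, 3) fit target
    selection: AtomSelection
    fit_selection: AtomSelection | None = None

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")


@dataclass
class FELGrid:
    xedges: np.ndarray
    yedges: np.ndarray
    free_energy: np.ndarray   # (nx, ny) kcal/mol, NaN where unoccupied
    temperature: float
    counts: np.ndarray | None = None  # histogram weights per bin
    kb: float = KB_KCAL

    @property
    def xcenters(self):
        return 0.5 * (self.xedges[:-1] + self.xedges[1:])

    @property
    def ycenters(self):
        return 0.5 * (self.yedges[:-1] + self.yedges[1:])


def _fitted_selection_coords(trajs, selection, reference, fit_selection=None):
    ref = reference.coord if isinstance(reference, StructureModel) else np.asarray(reference)
    fit_sel = fit_selection if fit_selection is not None else selection
    stacks = []
    for t in trajs:
        fitted = superpose_frames(t.coords, ref, fit_sel)
        stacks.append(fitted[:, selection.indices, :])
    return np.concatenate(stacks, axis=0)


def covariance_pca(traj: Trajectory | Sequence[Trajectory],
                   selection: AtomSelection,
                   reference: StructureModel,
                   fit_selection: AtomSelection | None = None) -> PCModel:
    """Diagonalize the covariance of fitted selection coordinates.

    Replica trajectories are concatenated after per-frame fitting to the
    shared reference (fitting uses ``fit_selection`` when given, otherwise
    the analysis selection itself).  Rank-deficient data is fine (zero
    eigenvalues); fewer than 2 frames or fewer than 3 selected atoms is an
    error.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if sum(t.n_frames for t in trajs) < 2:
        raise ValueError("PCA needs at least 2 frames")
    if len(selection) < 3:
        raise ValueError("PCA needs at least 3 selected atoms")
    coords = _fitted_selection_coords(trajs, selection, reference, fit_selection)
    f, n, _ = coords.shape
    x = coords.reshape(f, 3 * n)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / f
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    # deterministic sign: largest-magnitude component of each vector positive
    for k in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, k]))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    total = vals.sum()
    fractions = vals / total if total > 0 else np.zeros_like(vals)
    ref = reference.coord if isinstance(reference, StructureModel) else np.asarray(reference)
    return PCModel(mean=mean.reshape(n, 3), eigenvalues=vals, eigenvectors=vecs,
                   variance_fractions=fractions, reference_coords=ref,
                   selection=selection, fit_selection=fit_selection)


def project(traj: Trajectory | Sequence[Trajectory], model: PCModel,
            k: int = 2) -> np.ndarray:
    """Project fitted frames' deviations from the PCA mean onto the top-k PCs."""
    if k > model.eigenvectors.shape[1]:
        raise ValueError(f"k={k} exceeds the {model.eigenvectors.shape[1]} eigenvectors")
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    for t in trajs:
        if t.n_atoms <= model.selection.indices.max():
            raise ValueError("trajectory does not resolve the PCA selection")
    coords = _fitted_selection_coords(trajs, model.selection,
                                      model.reference_coords, model.fit_selection)
    x = coords.reshape(coords.shape[0], -1) - model.mean.reshape(-1)
    return x @ model.eigenvectors[:, :k]


def fel(projections: np.ndarray, temperature: float = DEFAULT_TEMPERATURE,
        bins: int | tuple = 80, weights: np.ndarray | None = None) -> FELGrid:
    """Boltzmann-inverted 2-D free-energy landscape over (PC1, PC2).

    ``weights`` optionally reweights frames (e.g. for reweighted ensembles);
    the density is then the weighted histogram.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("projections must be (frames, >=2)")
    counts, xe, ye = np.histogram2d(p[:, 0], p[:, 1], bins=bins, weights=weights)
    if counts.max() <= 0:
        raise ValueError("no occupied bins")
    with np.errstate(divide="ignore"):
        g = -KB_KCAL * temperature * np.log(counts / counts.max())
    g[counts == 0] = np.nan
    return FELGrid(xedges=xe, yedges=ye, free_energy=g,
                   temperature=temperature, counts=counts)


@dataclass
class Basin:
    location: tuple[float, float]  # (PC1, PC2) of the minimum bin center
    depth: float                   # kcal/mol relief to the separating saddle
    bin_index: tuple[int, int]


def basin_detect(grid: FELGrid, depth_threshold: float = 0.5,
                 min_support: int = 10) -> list[Basin]:
    """Persistent local minima of the landscape by grid flood-fill.

    Occupied bins are flooded in order of increasing ΔG (8-neighbor
    connectivity).  A basin that meets a deeper basin at level ``v`` merges
    into it unless its relief ``v - min`` exceeds ``depth_threshold``, in
    which case it is reported as a separate basin.  The deepest basin is
    always reported; its depth is the full occupied relief.

    ``min_support`` guards against Poisson shot noise: a reported basin's
    minimum bin must hold at least this many samples (the relative free-energy
    noise of a bin with count c is ~ k_B T / sqrt(c), so sparsely sampled tail
    bins would otherwise masquerade as shallow basins).  The global minimum is
    always kept.
    """
    g = grid.free_energy
    occupied = np.argwhere(np.isfinite(g))
    order = occupied[np.argsort(g[occupied[:, 0], occupied[:, 1]], kind="stable")]
    basin_of: dict[tuple[int, int], int] = {}
    minima: list[tuple[tuple[int, int], float]] = []  # (bin, min value) per basin
    persisted: dict[int, float] = {}
    parent: dict[int, int] = {}
    comp_max: dict[int, float] = {}  # highest flooded level per surviving root

    def find(b):
        while parent.get(b, b) != b:
            b = parent[b]
        return b

    for i, j in map(tuple, order):
        v = g[i, j]
        neigh = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                b = basin_of.get((i + di, j + dj))
                if b is not None:
                    neigh.add(find(b))
        if not neigh:
            b = len(minima)
            minima.append(((i, j), v))
            comp_max[b] = v
            basin_of[(i, j)] = b
            continue
        deepest = min(neigh, key=lambda b: minima[b][1])
        basin_of[(i, j)] = deepest
        comp_max[deepest] = max(comp_max[deepest], v)
        for b in neigh - {deepest}:
            relief = v - minima[b][1]
            if relief >= depth_threshold:
                persisted[b] = max(persisted.get(b, 0.0), relief)
            comp_max[deepest] = max(comp_max[deepest], comp_max.pop(b))
            parent[b] = deepest

    out = []
    roots = [b for b in range(len(minima)) if find(b) == b]
    global_root = min(roots, key=lambda b: minima[b][1])
    for b, ((i, j), vmin) in enumerate(minima):
        if find(b) == b:
            depth = comp_max[b] - vmin
            if depth < depth_threshold and b != global_root:
                continue
        elif b in persisted:
            depth = persisted[b]
        else:
            continue
        if (b != global_root and grid.counts is not None
                and grid.counts[i, j] < min_support):
            continue
        out.append(Basin(location=(float(grid.xcenters[i]), float(grid.ycenters[j])),
                         depth=float(depth), bin_index=(i, j)))
    out.sort(key=lambda b: -b.depth)
    return out
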