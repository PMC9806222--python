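"""Dynamical cross-correlation matrix (DCCM) of residue fluctuations.

For fitted frames, the covariance of displacement vectors about the ensemble
mean is ``c_ij = <Δr_i · Δr_j>`` and the normalized correlation is
``C_ij = c_ij / sqrt(c_ii c_jj)``, in [-1, 1].  Positive values mean residues
i and j move in the same direction, negative values anti-correlated motion.
One node per residue at its Cα is the convention used throughout.

Rigid-body motion must be removed before correlating: without fitting, a
uniformly translating ensemble yields an all-ones matrix.  Atoms with zero
fluctuation variance have undefined correlations and are flagged (NaN), not
divided by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .fit import superpose_frames
from .selections import AtomSelection
from .structure_io import StructureModel, Trajectory

MASK_SENTINEL = np.nan


@dataclass
class CorrelationMatrix:
    covariance: np.ndarray    # c_ij, Å²
    correlation: np.ndarray   # C_ij, unit diagonal where defined
    labels: list              # residue labels, matrix order
    undefined: np.ndarray     # bool per node: zero-variance flag

    @property
    def n(self) -> int:
        return self.correlation.shape[0]


def dccm(traj: Trajectory | Sequence[Trajectory], selection: AtomSelection,
         reference: StructureModel | None = None, align: bool = True
         ) -> CorrelationMatrix:
    """Residue-residue displacement correlation over (pooled) frames.

    With ``align=True`` (default) every frame is first rigid-body fitted on
    the selection to ``reference`` (defaults to the topology coordinates).
    Fluctuations are taken about the ensemble mean of the fitted coordinates.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if sum(t.n_frames for t in trajs) < 2:
        raise ValueError("DCCM needs at least 2 frames")
    topo = trajs[0].topology
    ref = (reference.coord if isinstance(reference, StructureModel)
           else reference if reference is not None else topo.coord)
    stacks = []
    for t in trajs:
        frames = superpose_frames(t.coords, ref, selection) if align else t.coords
        stacks.append(frames[:, selection.indices, :])
    x = np.concatenate(stacks, axis=0)
    dx = x - x.mean(axis=0, keepdims=True)
    f = dx.shape[0]
    cov = np.einsum("fid,fjd->ij", dx, dx) / f
    var = np.diag(cov).copy()
    undefined = var <= 1e-14
    denom = np.sqrt(np.where(undefined, 1.0, var))
    corr = cov / denom[:, None] / denom[None, :]
    corr[undefined, :] = np.nan
    corr[:, undefined] = np.nan
    d = np.arange(corr.shape[0])
    corr[d[~undefined], d[~undefined]] = 1.0
    labels = [
        f"{topo.chain[i]}:{topo.resname[i]}{topo.resid[i]}"
        for i in selection.indices
    ]
    return CorrelationMatrix(covariance=cov, correlation=corr,
                             labels=labels, undefined=undefined)


def dccm_replica_average(trajs: Sequence[Trajectory], selection, reference=None,
                         align: bool = True) -> CorrelationMatrix:
    """Per-replica DCCMs averaged elementwise (complement of pooled frames)."""
    mats = [dccm(t, selection, reference, align) for t in trajs]
    corr = np.mean([m.correlation for m in mats], axis=0)
    cov = np.mean([m.covariance for m in mats], axis=0)
    undefined = np.any([m.undefined for m in mats], axis=0)
    return CorrelationMatrix(covariance=cov, correlation=corr,
                             labels=mats[0].labels, undefined=undefined)


def mask_display(matrix: CorrelationMatrix, threshold: float = 0.4) -> np.ndarray:
    """Heatmap copy with |C| below ``threshold`` blanked (NaN); |C| exactly at
    the threshold is kept, and the diagonal always survives."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be a fraction in [0, 1]")
    c = matrix.correlation.copy()
    blank = np.abs(c) < threshold
    np.fill_diagonal(blank, False)
    c[blank] = MASK_SENTINEL
    return c


@dataclass
class InterdomainSummary:
    mean_correlation: float
    fraction_anticorrelated: float
    anti_cutoff: float
    n_pairs: int


def interdomain_summary(matrix: CorrelationMatrix, blockA, blockB,
                        anti_cutoff: float = -0.4) -> InterdomainSummary:
    """Statistics over the A×B sub-block of the correlation matrix.

    ``blockA``/``blockB`` are disjoint matrix-index sets (e.g. the residues of
    the kinase vs the residues of calmodulin); the summary reports the mean
    inter-block correlation and the fraction of pairs below ``anti_cutoff``.
    """
    a = np.asarray(blockA, dtype=int)
    b = np.asarray(blockB, dtype=int)
    if a.size == 0 or b.size == 0:
        raise SelectionError("blocks must be non-empty")
    if np.intersect1d(a, b).size:
        raise SelectionError("blocks must be disjoint")
    sub = matrix.correlation[np.ix_(a, b)]
    vals = sub[np.isfinite(sub)]
    return InterdomainSummary(
        mean_correlation=float(vals.mean()),
        fraction_anticorrelated=float(np.mean(vals < anti_cutoff)),
        anti_cutoff=anti_cutoff,
        n_pairs=int(vals.size),
    )
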