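"""Rigid-body superposition (Kabsch) and RMSD time series.

RMSD here is the plain geometric (unweighted) Cα convention: frames are
least-squares fitted on a *fit* selection and the deviation is then reported
on a *report* selection, which may differ — e.g. fit on the kinase core and
report the motion of the bound calmodulin relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError
from .selections import AtomSelection
from .structure_io import StructureModel, Trajectory


@dataclass
class SuperpositionResult:
    """Optimal proper rotation/translation and the post-fit RMSD (Å).

    The transform maps mobile coordinates onto the reference frame as
    ``x @ rotation + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation + self.translation


@dataclass
class RMSDSeries:
    values: np.ndarray     # per-frame RMSD, Å
    label: str             # report-selection label
    reference: str         # reference label
    mean: float
    sd: float

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


def _as_indices(selection) -> np.ndarray | slice:
    if selection is None:
        return slice(None)
    if isinstance(selection, AtomSelection):
        return selection.indices
    return np.asarray(selection, dtype=int)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Raw coordinate RMSD without fitting."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection=None) -> SuperpositionResult:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The fit is computed on ``selection`` (all atoms if None); reflections are
    excluded by the determinant correction, so the rotation is always proper.
    Fewer than 3 selected atoms, or a collinear selection, is an error
    because the rotation would not be unique.
    """
    idx = _as_indices(selection)
    p = np.asarray(mobile, dtype=float)[idx]
    q = np.asarray(reference, dtype=float)[idx]
    if p.shape != q.shape:
        raise DegenerateGeometryError(
            f"selection resolves to {p.shape[0]} mobile but {q.shape[0]} reference atoms"
        )
    if p.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    # collinearity check: rank of the centered cloud must be >= 2
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2 or np.linalg.matrix_rank(q0, tol=1e-8) < 2:
        raise DegenerateGeometryError("selection atoms are collinear; fit is degenerate")

    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    trans = qc - pc @ rot
    fitted = p @ rot + trans
    return SuperpositionResult(rotation=rot, translation=trans,
                               rmsd=rmsd_between(fitted, q))


def superpose_frames(coords: np.ndarray, reference: np.ndarray,
                     fit_selection=None) -> np.ndarray:
    """Fit every frame of ``coords`` (F, N, 3) onto ``reference`` (N, 3)."""
    out = np.empty_like(coords, dtype=float)
    for i in range(coords.shape[0]):
        res = kabsch_superpose(coords[i], reference, fit_selection)
        out[i] = res.apply(coords[i])
    return out


def rmsd_series(traj: Trajectory | Sequence[Trajectory],
                reference: StructureModel,
                fit_selection: AtomSelection,
                report_selection: AtomSelection | None = None,
                discard: int = 0) -> RMSDSeries:
    """Per-frame RMSD against a fixed reference.

    Each frame is rigid-body fitted on ``fit_selection`` and the RMSD is then
    evaluated on ``report_selection`` (defaults to the fit selection).  When a
    sequence of replica trajectories is given, all frames are pooled with
    equal weight into one series; use :func:`rmsd_series_per_replica` for the
    per-replica tables.  ``discard`` drops that many leading frames of each
    trajectory (equilibration), default 0.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    report = report_selection if report_selection is not None else fit_selection
    if len(fit_selection) == 0 or len(report) == 0:
        raise DegenerateGeometryError("fit/report selections must be non-empty")
    ridx = _as_indices(report)
    ref = reference.coord
    values = []
    for t in trajs:
        for f in range(discard, t.n_frames):
            res = kabsch_superpose(t.coords[f], ref, fit_selection)
            values.append(rmsd_between(res.apply(t.coords[f])[ridx], ref[ridx]))
    values = np.asarray(values)
    return RMSDSeries(values=values, label=report.label,
                      reference=reference.metadata.get("source", "reference"),
                      mean=float(values.mean()), sd=float(values.std()))


def rmsd_series_per_replica(trajs: Sequence[Trajectory], reference, fit_selection,
                            report_selection=None, discard: int = 0) -> list[RMSDSeries]:
    return [rmsd_series(t, reference, fit_selection, report_selection, discard)
            for t in trajs]
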