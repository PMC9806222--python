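"""Radial distribution functions, coordination numbers, coordination modes.

``rdf`` histograms center-target distances into shells of width ``bin_width``
and normalizes by shell volume 4πr²dr, frame count, center count and the bulk
number density, so an ideal uniform target gives g(r) = 1.  The running
coordination integral ``n(r) = ρ ∫ 4πs² g(s) ds`` is the average number of
target particles within r of a center; evaluated at the first minimum after
the first peak it is the coordination number.

``coordination_mode`` catalogues, for a single structure, every oxygen within
a cutoff of an ion, categorised as sidechain O / backbone O / water O —
bidentate carboxylates contribute two records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (AMINO_ACIDS, COORDINATION_CUTOFF, RDF_BIN_WIDTH,
                        RDF_R_MAX, WATER_RESNAMES)
from .errors import SelectionError
from .selections import AtomSelection
from .structure_io import StructureModel, Trajectory


@dataclass
class RDFProfile:
    bin_edges: np.ndarray
    g: np.ndarray
    n_running: np.ndarray     # n(r) at the right edge of each bin
    density: float            # bulk number density used for normalization, Å^-3
    center_label: str
    target_label: str
    periodic: bool

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class LigandRecord:
    resname: str
    resid: int
    atom_name: str
    category: str             # 'sidechain O' | 'backbone O' | 'water O'


@dataclass
class CoordinationShell:
    ion_index: int
    cutoff: float
    ligands: list

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)


def _pair_distances(centers: np.ndarray, targets: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    d = targets[None, :, :] - centers[:, None, :]
    if box is not None:
        d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=2).ravel()


def rdf(traj: Trajectory, center: AtomSelection, target: AtomSelection,
        bin_width: float = RDF_BIN_WIDTH, r_max: float = RDF_R_MAX,
        density: float | None = None) -> RDFProfile:
    """Radial pair distribution function between two selections.

    Minimum-image distances are used when the trajectory carries box vectors
    (``r_max`` must then be at most half the smallest box edge).  The bulk
    density defaults to target count / box volume; without a box it must be
    given explicitly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(center) == 0 or len(target) == 0:
        raise SelectionError("center and target selections must be non-empty")
    periodic = traj.box is not None
    if periodic and r_max > 0.5 * traj.box.min() + 1e-9:
        raise ValueError("r_max must be at most half the minimum box dimension")
    if density is None:
        if not periodic:
            raise ValueError("bulk density must be given for a non-periodic system")
        density = len(target) / float(np.prod(traj.box.mean(axis=0)))

    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    overlap = len(np.intersect1d(center.indices, target.indices))
    for f in range(traj.n_frames):
        box = traj.box[f] if periodic else None
        dist = _pair_distances(traj.coords[f][center.indices],
                               traj.coords[f][target.indices], box)
        counts += np.histogram(dist, bins=edges)[0]
    if overlap:  # self-distances land in the first bin; remove them
        counts[0] -= overlap * traj.n_frames

    norm = traj.n_frames * len(center)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (norm * shell_vol * density)
    n_running = np.cumsum(counts) / norm
    return RDFProfile(bin_edges=edges, g=g, n_running=n_running, density=density,
                      center_label=center.label, target_label=target.label,
                      periodic=periodic)


def first_shell_minimum(profile: RDFProfile, smooth_window: int = 5) -> float:
    """First local minimum of a smoothed g(r) after the first peak."""
    g = profile.g
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    centers = profile.bin_centers
    # a genuine first-shell peak clearly exceeds the bulk level of 1
    peaks = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:]) & (g[1:-1] > 2.0))
    if peaks.size == 0:
        raise ValueError("no first-shell peak found; pass an explicit cutoff")
    p = peaks[0] + 1
    for i in range(p + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
            return float(centers[i])
    raise ValueError("no minimum after the first peak; pass an explicit cutoff")


def coordination_number(profile: RDFProfile,
                        first_minimum: float | None = None) -> float:
    """Running coordination integral n(r) evaluated at the first minimum."""
    r = first_minimum if first_minimum is not None else first_shell_minimum(profile)
    if not (profile.bin_edges[0] <= r <= profile.bin_edges[-1]):
        raise ValueError("first_minimum outside the profile range")
    return float(np.interp(r, profile.bin_edges[1:], profile.n_running))


def _oxygen_category(model: StructureModel, i: int) -> str | None:
    if model.element[i].upper() != "O":
        return None
    resname = str(model.resname[i])
    if resname in WATER_RESNAMES:
        return "water O"
    if resname in AMINO_ACIDS:
        return "backbone O" if model.name[i] in ("O", "OXT") else "sidechain O"
    return "other O"


def coordination_mode(structure: StructureModel, ion: int,
                      cutoff: float = COORDINATION_CUTOFF) -> CoordinationShell:
    """Catalogue every oxygen within ``cutoff`` of atom index ``ion``.

    Each coordinating oxygen is one record (a bidentate carboxylate appears
    twice, once per oxygen).  An empty shell is a valid result, not an error.
    """
    if not (0 <= ion < structure.n_atoms):
        raise SelectionError(f"ion atom index {ion} out of range")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.linalg.norm(structure.coord - structure.coord[ion], axis=1)
    ligands = []
    for i in np.flatnonzero((d <= cutoff) & (d > 1e-9)):
        cat = _oxygen_category(structure, int(i))
        if cat is None:
            continue
        ligands.append(LigandRecord(resname=str(structure.resname[i]),
                                    resid=int(structure.resid[i]),
                                    atom_name=str(structure.name[i]),
                                    category=cat))
    return CoordinationShell(ion_index=ion, cutoff=cutoff, ligands=ligands)


def coordination_mode_trajectory(traj: Trajectory, ion: int,
                                 cutoff: float = COORDINATION_CUTOFF):
    """Per-frame coordination scan; returns (majority CN, per-frame CNs)."""
    cns = []
    for f in range(traj.n_frames):
        model = traj.topology.with_coordinates(traj.coords[f])
        cns.append(coordination_mode(model, ion, cutoff).coordination_number)
    cns = np.asarray(cns)
    values, freq = np.unique(cns, return_counts=True)
    return int(values[np.argmax(freq)]), cns
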