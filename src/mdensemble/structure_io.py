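"""Structures, trajectories and atom selections.

A :class:`StructureModel` is a flat, ordered table of atoms (column arrays),
the container every analysis stage works against.  PDB parsing/writing is
delegated to biotite; DCD/XTC trajectory I/O is delegated to MDAnalysis
coordinate readers.  Residue numbering is kept exactly as in the source file
so residue labels used in the literature (Asp56, Glu104, ...) map directly.

Alternate locations: only one conformer per atom is retained — the one with
the highest occupancy, ties broken by the alphabetically first altloc letter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AtomCountMismatchError,
    EmptyModelError,
    StructureFormatError,
    TrajectoryTruncationError,
)
from .selections import AtomSelection, evaluate_selection


@dataclass
class StructureModel:
    """Ordered atom records of one structural model, coordinates in Å."""

    serial: np.ndarray      # int
    name: np.ndarray        # str, PDB atom names
    resname: np.ndarray     # str
    resid: np.ndarray       # int, as in source
    icode: np.ndarray       # str, insertion codes ('' if none)
    chain: np.ndarray       # str
    element: np.ndarray     # str, upper-case symbols
    occupancy: np.ndarray   # float
    altloc: np.ndarray      # str, retained conformer letter ('' if none)
    hetero: np.ndarray      # bool, True for HETATM records
    coord: np.ndarray       # (N, 3) float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ValueError("coord must be (N, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def select(self, expression: str, label: str | None = None) -> AtomSelection:
        return select_atoms(self, expression, label=label)

    def subset(self, indices: np.ndarray | AtomSelection) -> "StructureModel":
        idx = indices.indices if isinstance(indices, AtomSelection) else np.asarray(indices)
        return StructureModel(
            serial=self.serial[idx], name=self.name[idx], resname=self.resname[idx],
            resid=self.resid[idx], icode=self.icode[idx], chain=self.chain[idx],
            element=self.element[idx], occupancy=self.occupancy[idx],
            altloc=self.altloc[idx], hetero=self.hetero[idx],
            coord=self.coord[idx].copy(), metadata=dict(self.metadata),
        )

    def with_coordinates(self, coord: np.ndarray) -> "StructureModel":
        out = self.subset(np.arange(self.n_atoms))
        out.coord = np.asarray(coord, dtype=float).copy()
        return out

    def residue_keys(self) -> list[tuple]:
        """Unique (chain, resid, icode, resname) keys in atom order."""
        seen, keys = set(), []
        for ch, ri, ic, rn in zip(self.chain, self.resid, self.icode, self.resname):
            k = (str(ch), int(ri), str(ic), str(rn))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates bound to a topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å. ``box`` optionally holds
    per-frame orthorhombic box edge lengths (n_frames, 3) in Å; ``times`` holds
    optional per-frame time stamps in ns.
    """

    topology: StructureModel
    coords: np.ndarray
    times: np.ndarray | None = None
    box: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise AtomCountMismatchError(
                f"trajectory has {self.coords.shape[1]} atoms per frame but the "
                f"topology has {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coords[i]


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

def _apply_altloc_policy(order, keys, occupancies, altlocs):
    """Indices keeping, per atom site, the highest-occupancy conformer.

    Ties broken by the alphabetically first altloc letter.  ``order`` is the
    candidate index array; ``keys`` identifies the atom site of each candidate.
    """
    best: dict = {}
    for i in order:
        k = keys[i]
        if k not in best:
            best[k] = i
            continue
        j = best[k]
        if (occupancies[i], _neg_letter(altlocs[i])) > (occupancies[j], _neg_letter(altlocs[j])):
            best[k] = i
    kept = sorted(best.values())
    return np.asarray(kept, dtype=int)


def _neg_letter(letter: str):
    # sort helper: higher tuple wins, so earlier letters must compare greater
    return tuple(-ord(c) for c in letter)


def read_structure(path, format: str = "pdb", model: int = 1) -> StructureModel:
    """Read a structure file into a :class:`StructureModel`.

    Only the PDB format is supported.  All ATOM and HETATM records of the
    requested model are exposed; alternate locations are reduced to a single
    conformer per site (highest occupancy, ties by altloc letter).
    """
    if format.lower() != "pdb":
        raise StructureFormatError(f"unsupported structure format: {format!r}")
    path = Path(path)
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(
            model=model, altloc="all",
            extra_fields=["atom_id", "occupancy"],
        )
    except Exception as exc:  # biotite raises various types; find the bad line
        line_hint = _find_bad_pdb_line(path)
        raise StructureFormatError(
            f"could not parse {path} as PDB{line_hint}: {exc}"
        ) from exc
    if atoms.array_length() == 0:
        raise EmptyModelError(f"{path} contains no atoms in model {model}")

    occ = atoms.occupancy
    alt = atoms.altloc_id if "altloc_id" in atoms.get_annotation_categories() else \
        np.array([""] * atoms.array_length())
    alt = np.char.strip(alt.astype(str))
    alt[alt == "."] = ""
    site_keys = [
        (c, int(r), str(ic), str(rn), str(an))
        for c, r, ic, rn, an in zip(
            atoms.chain_id, atoms.res_id, atoms.ins_code,
            atoms.res_name, atoms.atom_name,
        )
    ]
    kept = _apply_altloc_policy(np.arange(atoms.array_length()), site_keys, occ, alt)

    return StructureModel(
        serial=atoms.atom_id[kept].astype(int),
        name=atoms.atom_name[kept].astype(str),
        resname=atoms.res_name[kept].astype(str),
        resid=atoms.res_id[kept].astype(int),
        icode=np.char.strip(atoms.ins_code[kept].astype(str)),
        chain=np.char.strip(atoms.chain_id[kept].astype(str)),
        element=np.char.upper(atoms.element[kept].astype(str)),
        occupancy=occ[kept].astype(float),
        altloc=alt[kept],
        hetero=atoms.hetero[kept].astype(bool),
        coord=atoms.coord[kept].astype(float),
        metadata={"source": str(path), "format": "pdb", "model": model},
    )


def _find_bad_pdb_line(path) -> str:
    try:
        with open(path) as fh:
            for n, line in enumerate(fh, 1):
                if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                    return f" (line {n})"
    except OSError:
        pass
    return ""


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    atoms = struc.AtomArray(model.n_atoms)
    atoms.coord = model.coord.astype(np.float32)
    atoms.chain_id = model.chain
    atoms.res_id = model.resid
    atoms.ins_code = model.icode
    atoms.res_name = model.resname
    atoms.atom_name = model.name
    atoms.element = model.element
    atoms.hetero = model.hetero
    atoms.set_annotation("occupancy", model.occupancy.astype(float))
    atoms.set_annotation("b_factor", np.zeros(model.n_atoms))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Trajectory reading / writing (MDAnalysis-backed)
# ---------------------------------------------------------------------------

_PS_PER_NS = 1000.0


def _dcd_header_frames(path: Path) -> int | None:
    """Frame count promised by a DCD header (NSET), or None if unreadable.

    Readers that infer the frame count from the file size silently swallow a
    trailing partial frame; the header value lets truncation be detected.
    """
    import struct

    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
        if len(head) < 12 or head[4:8] != b"CORD":
            return None
        nset = struct.unpack("<i", head[8:12])[0]
        return nset if nset > 0 else None
    except OSError:
        return None


def _reader_for(path: Path):
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    suffix = path.suffix.lower()
    if suffix == ".dcd":
        return DCDReader
    if suffix == ".xtc":
        return XTCReader
    raise StructureFormatError(f"unsupported trajectory format: {suffix!r}")


def read_trajectory(path, topology: StructureModel) -> Trajectory:
    """Read a DCD/XTC trajectory against ``topology``.

    Frames are loaded in order; a file that ends mid-frame raises
    :class:`TrajectoryTruncationError` naming the last complete frame.
    """
    path = Path(path)
    reader_cls = _reader_for(path)
    try:
        reader = reader_cls(str(path))
    except Exception as exc:
        raise StructureFormatError(f"could not open trajectory {path}: {exc}") from exc

    if reader.n_atoms != topology.n_atoms:
        raise AtomCountMismatchError(
            f"trajectory {path} has {reader.n_atoms} atoms but the topology "
            f"has {topology.n_atoms}"
        )

    frames, times, boxes = [], [], []
    expected = None
    if path.suffix.lower() == ".dcd":
        expected = _dcd_header_frames(path)
    if expected is None:
        try:
            expected = len(reader)
        except Exception:
            pass
    try:
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=float))
            times.append(float(ts.time) / _PS_PER_NS)
            dims = ts.dimensions
            boxes.append(np.array(dims[:3], dtype=float) if dims is not None else None)
    except (OSError, EOFError, ValueError, RuntimeError) as exc:
        last = len(frames) - 1
        raise TrajectoryTruncationError(
            f"trajectory {path} is truncated: last complete frame is {last} "
            f"(0-based); read {len(frames)} of {expected or '?'} expected frames",
            last_complete_frame=last,
        ) from exc
    finally:
        reader.close()
    if expected is not None and len(frames) < expected:
        last = len(frames) - 1
        raise TrajectoryTruncationError(
            f"trajectory {path} is truncated: header promises {expected} frames "
            f"but only {len(frames)} complete frames are present; last complete "
            f"frame is {last} (0-based)",
            last_complete_frame=last,
        )
    if not frames:
        raise EmptyModelError(f"trajectory {path} contains no complete frames")

    box = None
    if all(b is not None for b in boxes) and boxes:
        box = np.stack(boxes)
        if not box.any():
            box = None
    return Trajectory(
        topology=topology,
        coords=np.stack(frames),
        times=np.asarray(times),
        box=box,
        metadata={"source": str(path), "format": path.suffix.lstrip(".").lower()},
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames to DCD or XTC (by file extension)."""
    import MDAnalysis as mda

    path = Path(path)
    n = traj.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n_atoms=n) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coords[i].astype(np.float32)
            if traj.box is not None:
                u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
            if traj.times is not None:
                u.trajectory.ts.time = traj.times[i] * _PS_PER_NS
            u.trajectory.ts.frame = i
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_atoms(model: StructureModel, expression: str,
                 label: str | None = None) -> AtomSelection:
    """Resolve a selection expression to an ordered, unique index list.

    The mini-grammar supports ``name``, ``resname``, ``resid`` (values and
    ``a-b`` ranges), ``chain``, ``element``, ``water``, ``protein``,
    ``hetero``, ``all``, combined with ``and``/``or``/``not`` and parentheses.
    An empty result is allowed but reported with a warning.
    """
    mask = evaluate_selection(model, expression)
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return AtomSelection(indices=indices, expression=expression,
                         label=label or expression)
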