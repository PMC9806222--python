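"""Synthetic ensembles with known ground truth.

Downstream stages (PCA/FEL, cross-correlation, networks, clustering, RDF)
are validated against ensembles whose statistical structure is prescribed
exactly:

* Gaussian fluctuation ensembles with a target residue-residue displacement
  correlation matrix (block-correlated / anti-correlated inter-domain blocks),
* two-substate conformational mixtures with known labels,
* an ion + solvation-shell toy with a first shell at a stated radius and an
  ideal-gas bulk.

Displacements are isotropic per particle: the same correlated scalar draw is
applied independently to x, y and z, which makes the displacement-vector
correlation ground truth *exactly* the target matrix.  Correlated draws use
the symmetric eigendecomposition square root ``L = V sqrt(max(Λ, 0)) Vᵀ`` of
the target matrix; this factorization is part of the contract and stable
across versions.  Identical spec + seed reproduces the trajectory bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotPositiveSemiDefiniteError, PlacementError
from .structure_io import StructureModel, Trajectory

_PSD_TOL = 1e-10


@dataclass
class EnsembleSpec:
    """Prescription for a correlated Gaussian fluctuation ensemble."""

    reference: np.ndarray       # (N, 3) Å
    correlation: np.ndarray     # (N, N) target, unit diagonal, PSD
    amplitudes: np.ndarray      # (N,) per-particle RMS fluctuation per axis, Å
    n_frames: int
    seed: int

    def validate(self) -> None:
        c = np.asarray(self.correlation, dtype=float)
        n = self.reference.shape[0]
        if c.shape != (n, n):
            raise ValueError("correlation matrix shape must match particle count")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("target correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("target correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -_PSD_TOL * max(1.0, np.abs(c).max()):
            raise NotPositiveSemiDefiniteError(
                "target correlation matrix is not positive semi-definite"
            )
        if np.any(np.asarray(self.amplitudes) <= 0):
            raise ValueError("fluctuation amplitudes must be positive")
        if self.n_frames < 1:
            raise ValueError("frame count must be >= 1")


@dataclass
class SolvationToySpec:
    """Prescription for an ion + first-shell + ideal-gas-bulk toy system."""

    ion_position: np.ndarray    # (3,) Å
    shell_radius: float         # Å
    shell_occupancy: int
    box: np.ndarray             # (3,) orthorhombic edge lengths, Å
    bulk_density: float         # Å^-3
    jitter: float               # Å, radial SD of shell particles
    n_frames: int
    seed: int

    def validate(self) -> None:
        box = np.asarray(self.box, dtype=float)
        if self.shell_radius >= 0.5 * box.min():
            raise ValueError("shell radius must be below half the box minimum dimension")
        if self.shell_occupancy < 0:
            raise ValueError("shell occupancy must be >= 0")
        if self.bulk_density < 0 or self.jitter < 0:
            raise ValueError("density and jitter must be non-negative")
        if self.n_frames < 1:
            raise ValueError("frame count must be >= 1")


# ---------------------------------------------------------------------------
# topology helpers
# ---------------------------------------------------------------------------

def make_chain_topology(n_residues: int, chains: dict[str, int] | None = None,
                        spacing: float = 3.8) -> StructureModel:
    """Pseudo-Cα chain: one ALA CA per residue on a loose helix.

    ``chains`` maps chain id -> residue count (insertion order preserved);
    default is a single chain A.  Residues are numbered from 1 per chain.
    """
    chains = chains or {"A": n_residues}
    total = sum(chains.values())
    if total != n_residues:
        raise ValueError("chain residue counts must sum to n_residues")
    # alpha-helix-like trace: 2.3 Å radius, 100 deg per residue, 1.5 Å rise,
    # so Ca(i)-Ca(i+1) ~ 3.8 Å and i+/-3, i+/-4 neighbors sit within ~6 Å
    t = np.arange(n_residues, dtype=float)
    ang = np.deg2rad(100.0) * t
    coord = np.column_stack([
        2.3 * np.cos(ang), 2.3 * np.sin(ang), (spacing / 3.8) * 1.5 * t,
    ])
    chain_ids, resids = [], []
    for cid, cnt in chains.items():
        chain_ids += [cid] * cnt
        resids += list(range(1, cnt + 1))
    n = n_residues
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array(["CA"] * n), resname=np.array(["ALA"] * n),
        resid=np.array(resids, dtype=int), icode=np.array([""] * n),
        chain=np.array(chain_ids), element=np.array(["C"] * n),
        occupancy=np.ones(n), altloc=np.array([""] * n),
        hetero=np.zeros(n, dtype=bool), coord=coord,
        metadata={"source": "synthetic chain", "format": "memory", "model": 1},
    )


def block_correlation(n: int, blocks: list[tuple[int, int]],
                      intra: float, inter: float) -> np.ndarray:
    """Block-structured target matrix: ``intra`` within each block, ``inter``
    between different blocks, unit diagonal.  ``blocks`` are [start, stop)
    index ranges covering 0..n."""
    member = np.full(n, -1)
    for b, (lo, hi) in enumerate(blocks):
        member[lo:hi] = b
    if np.any(member < 0):
        raise ValueError("blocks must cover all particles")
    same = member[:, None] == member[None, :]
    c = np.where(same, intra, inter).astype(float)
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# correlated ensembles
# ---------------------------------------------------------------------------

def _correlation_sqrt(c: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def generate_correlated_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Independent frames of reference + correlated Gaussian displacements.

    Per frame and per Cartesian axis, a correlated standard-normal vector
    ``z = L u`` (with ``L`` the symmetric PSD square root of the target) is
    scaled by the per-particle amplitudes, so empirical displacement-vector
    correlations converge to the target as the frame count grows.
    """
    spec.validate()
    n = spec.reference.shape[0]
    sqrt_c = _correlation_sqrt(np.asarray(spec.correlation, dtype=float))
    rng = np.random.default_rng(spec.seed)
    amps = np.asarray(spec.amplitudes, dtype=float)
    # (frames, axes, particles) standard normals -> correlate across particles
    u = rng.standard_normal((spec.n_frames, 3, n))
    z = u @ sqrt_c.T
    disp = np.transpose(z, (0, 2, 1)) * amps[None, :, None]
    coords = spec.reference[None, :, :] + disp
    topo = make_chain_topology(n).with_coordinates(spec.reference)
    return Trajectory(topology=topo, coords=coords,
                      metadata={"generator": "correlated_ensemble", "seed": spec.seed})


def generate_two_state_ensemble(specA: EnsembleSpec, specB: EnsembleSpec,
                                weightA: float, seed: int | None = None
                                ) -> tuple[Trajectory, np.ndarray]:
    """Labeled mixture of two fluctuation ensembles (true labels returned).

    Frame counts are taken from ``specA.n_frames`` (the mixture length);
    both specs must share the particle count, and ``weightA`` must define a
    proper mixture (0 < weightA < 1).
    """
    if specA.reference.shape[0] != specB.reference.shape[0]:
        raise ValueError("specs must share the particle count")
    if not (0.0 < weightA < 1.0):
        raise ValueError("weightA must be strictly between 0 and 1 (proper mixture)")
    specA.validate()
    specB.validate()
    n_frames = specA.n_frames
    rng = np.random.default_rng(specA.seed if seed is None else seed)
    labels = (rng.random(n_frames) >= weightA).astype(int)  # 0 -> A, 1 -> B
    trajA = generate_correlated_ensemble(
        EnsembleSpec(specA.reference, specA.correlation, specA.amplitudes,
                     n_frames, specA.seed))
    trajB = generate_correlated_ensemble(
        EnsembleSpec(specB.reference, specB.correlation, specB.amplitudes,
                     n_frames, specB.seed))
    coords = np.where(labels[:, None, None] == 0, trajA.coords, trajB.coords)
    traj = Trajectory(topology=trajA.topology, coords=coords,
                      metadata={"generator": "two_state_ensemble",
                                "weightA": weightA, "seed": specA.seed})
    return traj, labels


# ---------------------------------------------------------------------------
# solvation toy
# ---------------------------------------------------------------------------

def _solvation_topology(spec: SolvationToySpec, n_bulk: int) -> StructureModel:
    n = 1 + spec.shell_occupancy + n_bulk
    names = ["CA"] + ["O"] * (n - 1)
    resnames = ["CAL"] + ["HOH"] * (n - 1)
    elements = ["CA"] + ["O"] * (n - 1)
    coord = np.zeros((n, 3))
    coord[0] = spec.ion_position
    return StructureModel(
        serial=np.arange(1, n + 1), name=np.array(names),
        resname=np.array(resnames), resid=np.arange(1, n + 1),
        icode=np.array([""] * n), chain=np.array(["W"] * n),
        element=np.array(elements), occupancy=np.ones(n),
        altloc=np.array([""] * n),
        hetero=np.ones(n, dtype=bool), coord=coord,
        metadata={"source": "synthetic solvation toy", "format": "memory"},
    )


def generate_solvation_toy(spec: SolvationToySpec,
                           max_retries: int = 200) -> Trajectory:
    """Fixed ion + jittered first shell + uniform ideal-gas bulk.

    Shell particles sit at ``shell_radius`` ± ``jitter`` in uniformly random
    directions.  Bulk particles are uniform in the box excluding a sphere of
    radius ``shell_radius + 3*jitter + 0.5 Å`` around the ion (ideal gas — no
    excluded volume among themselves), so g(r) → 1 analytically at large r.
    """
    spec.validate()
    box = np.asarray(spec.box, dtype=float)
    ion = np.asarray(spec.ion_position, dtype=float)
    exclusion = spec.shell_radius + 3.0 * spec.jitter + 0.5
    n_bulk = int(round(spec.bulk_density * np.prod(box)))
    rng = np.random.default_rng(spec.seed)

    frames = np.empty((spec.n_frames, 1 + spec.shell_occupancy + n_bulk, 3))
    for f in range(spec.n_frames):
        frames[f, 0] = ion
        if spec.shell_occupancy:
            v = rng.standard_normal((spec.shell_occupancy, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            r = spec.shell_radius + spec.jitter * rng.standard_normal(spec.shell_occupancy)
            frames[f, 1:1 + spec.shell_occupancy] = ion + v * r[:, None]
        placed = 0
        tries = 0
        pts = np.empty((n_bulk, 3))
        while placed < n_bulk:
            if tries > max_retries:
                raise PlacementError(
                    f"could not place {n_bulk} bulk particles outside the shell "
                    f"exclusion after {max_retries} retries"
                )
            cand = rng.random((n_bulk - placed, 3)) * box
            d = cand - ion
            d -= box * np.round(d / box)
            ok = np.linalg.norm(d, axis=1) > exclusion
            k = int(ok.sum())
            pts[placed:placed + k] = cand[ok]
            placed += k
            tries += 1
        frames[f, 1 + spec.shell_occupancy:] = pts

    topo = _solvation_topology(spec, n_bulk)
    return Trajectory(
        topology=topo, coords=frames,
        box=np.tile(box, (spec.n_frames, 1)),
        metadata={"generator": "solvation_toy", "seed": spec.seed,
                  "bulk_density": spec.bulk_density, "n_bulk": n_bulk},
    )


# ---------------------------------------------------------------------------
# synthetic coordination-site models
# ---------------------------------------------------------------------------

def build_ns2_site(scale: float = 2.4) -> StructureModel:
    """SYNTHETIC reconstruction of the NS2 EF-hand Ca²⁺ site of calmodulin.

    The deposited crystal coordinates are not bundled; this model places the
    published sevenfold pentagonal-bipyramidal ligand set — sidechain oxygens
    of Asp56, Asp58, Asn60, Asp64, the backbone carbonyl of Thr62 and both
    carboxylate oxygens of Glu67 — at ``scale`` Å around a central Ca²⁺, with
    the parent carbon/nitrogen scaffold pointing outward.  It is a geometric
    stand-in for the deposited structure, suitable for exercising
    coordination-mode cataloguing, not a crystallographic model.
    """
    ca_pos = np.zeros(3)
    # 5 equatorial vertices + 2 axial
    ang = np.deg2rad(72.0) * np.arange(5)
    vertices = [np.array([np.cos(a), np.sin(a), 0.0]) for a in ang]
    vertices += [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    # (resname, resid, ligand atom name) in vertex order; Glu67 is bidentate
    ligands = [
        ("ASP", 56, "OD1"), ("ASP", 58, "OD1"), ("ASN", 60, "OD1"),
        ("ASP", 64, "OD1"), ("GLU", 67, "OE1"),
        ("THR", 62, "O"), ("GLU", 67, "OE2"),
    ]
    serial, names, resnames, resids, elements, hetero, coords = [], [], [], [], [], [], []

    def add(name, resname, resid, element, xyz, het=False):
        serial.append(len(serial) + 1)
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        elements.append(element)
        hetero.append(het)
        coords.append(xyz)

    add("CA", "CA", 200, "CA", ca_pos, het=True)
    parent_of = {"OD1": "CG", "OE1": "CD", "OE2": "CG", "O": "C"}
    for (resname, resid, aname), v in zip(ligands, vertices):
        add(aname, resname, resid, "O", v * scale)
        # outward parent carbon so the oxygen is recognisably side/backbone
        add(parent_of[aname], resname, resid, "C", v * (scale + 1.25))
        if aname == "O":  # give the backbone carbonyl its residue context
            add("CA", resname, resid, "C", v * (scale + 2.5))

    n = len(serial)
    return StructureModel(
        serial=np.array(serial), name=np.array(names), resname=np.array(resnames),
        resid=np.array(resids, dtype=int), icode=np.array([""] * n),
        chain=np.array(["B"] * n), element=np.array(elements),
        occupancy=np.ones(n), altloc=np.array([""] * n),
        hetero=np.array(hetero), coord=np.array(coords, dtype=float),
        metadata={"source": "synthetic NS2 EF-hand site", "format": "memory"},
    )


def build_four_site_model() -> StructureModel:
    """SYNTHETIC holo-calmodulin-like model with four Ca²⁺ sites.

    Four translated copies of the NS2-style site stand in for the two N-lobe
    and two C-lobe EF-hand sites; used to exercise calcium-heteroatom reading
    and per-site scans without the deposited structure.
    """
    parts = []
    shift = np.array([25.0, 0.0, 0.0])
    base = build_ns2_site()
    resid_offset = 0
    for i in range(4):
        m = base.with_coordinates(base.coord + i * shift)
        m.resid = m.resid + resid_offset
        parts.append(m)
        resid_offset += 100

    def cat(attr):
        return np.concatenate([getattr(p, attr) for p in parts])

    n = sum(p.n_atoms for p in parts)
    return StructureModel(
        serial=np.arange(1, n + 1), name=cat("name"), resname=cat("resname"),
        resid=cat("resid"), icode=cat("icode"), chain=cat("chain"),
        element=cat("element"), occupancy=cat("occupancy"), altloc=cat("altloc"),
        hetero=cat("hetero"), coord=np.concatenate([p.coord for p in parts]),
        metadata={"source": "synthetic four-site holo model", "format": "memory"},
    )


# ---------------------------------------------------------------------------
# host-guest binding toy (for the energetics stage)
# ---------------------------------------------------------------------------

def generate_binding_toy(n_frames: int = 20, seed: int = 0,
                         separation: float = 4.0, jitter: float = 0.05):
    """Small two-chain host-guest system with per-atom parameters.

    Returns ``(Trajectory, charges, rstar, epsilon, gb_radius, receptor_idx,
    ligand_idx)``.  The receptor is a 6-atom ring (chain R), the ligand a
    3-atom probe (chain L) ``separation`` Å above it; frames add Gaussian
    jitter so energy terms have a genuine frame-to-frame spread.
    """
    rng = np.random.default_rng(seed)
    ring = np.array([[np.cos(a), np.sin(a), 0.0]
                     for a in np.deg2rad(60.0) * np.arange(6)]) * 2.5
    probe = np.array([[0.0, 0.0, separation],
                      [1.2, 0.0, separation],
                      [-1.2, 0.0, separation]])
    ref = np.vstack([ring, probe])
    n = ref.shape[0]
    charges = np.array([0.3, -0.3, 0.3, -0.3, 0.3, -0.3, -0.6, 0.3, 0.3])
    rstar = np.full(n, 1.7)
    epsilon = np.full(n, 0.1)
    gb_radius = np.full(n, 1.5)
    coords = ref[None] + jitter * rng.standard_normal((n_frames, n, 3))
    topo = StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array([f"C{i+1}" for i in range(6)] + ["O1", "H1", "H2"]),
        resname=np.array(["RNG"] * 6 + ["LIG"] * 3),
        resid=np.array([1] * 6 + [2] * 3), icode=np.array([""] * n),
        chain=np.array(["R"] * 6 + ["L"] * 3),
        element=np.array(["C"] * 6 + ["O", "H", "H"]),
        occupancy=np.ones(n), altloc=np.array([""] * n),
        hetero=np.zeros(n, dtype=bool), coord=ref,
        metadata={"source": "synthetic binding toy", "format": "memory"},
    )
    traj = Trajectory(topology=topo, coords=coords,
                      metadata={"generator": "binding_toy", "seed": seed})
    return traj, charges, rstar, epsilon, gb_radius, np.arange(6), np.arange(6, 9)
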