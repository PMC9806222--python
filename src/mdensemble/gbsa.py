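"""MM-GBSA-style interaction-energy decomposition.

End-point binding energetics over trajectory snapshots (single-trajectory
protocol: complex, receptor and ligand geometries come from the same frame,
so internal gas-phase terms cancel and the gas contribution reduces to
receptor-ligand cross terms):

    dG_binding   = G(complex) - G(receptor) - G(ligand)
    dE_gas       = dE_vdW + dE_ele
    dG_solvation = dG_GB + dG_nonpolar
    dG_nonpolar  = gamma * dSASA + b

The polar term is pairwise generalized Born,
``-0.5 (1/eps_in - 1/eps_out) k_e sum_ij q_i q_j / f_GB`` with
``f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j)))``; effective Born radii
come from Hawkins-Cramer-Truhlar pairwise descreening.  The nonpolar term is
a Shrake-Rupley solvent-accessible surface area times gamma (default 0.0072
kcal/mol/Å², b = 0).  The solute-entropy term is not computed.

Per-atom parameters (charge, Lennard-Jones R*/epsilon, intrinsic GB radius)
arrive via :class:`ForceFieldParams`, loadable from a plain-text table —
see :meth:`ForceFieldParams.from_table`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (B_SASA, GAMMA_SASA, K_COULOMB, SASA_POINTS, SASA_PROBE,
                        SOLUTE_DIELECTRIC, SOLVENT_DIELECTRIC)
from .errors import SelectionError
from .selections import AtomSelection
from .structure_io import Trajectory

_IDENTITY_TOL = 1e-9


@dataclass
class ForceFieldParams:
    """Per-atom nonbonded parameters.

    Lennard-Jones combination is Lorentz-Berthelot on the R*/epsilon
    convention: pair minimum at ``R*_i + R*_j`` with depth ``sqrt(e_i e_j)``.
    """

    charge: np.ndarray    # e
    rstar: np.ndarray     # Å
    epsilon: np.ndarray   # kcal/mol
    gb_radius: np.ndarray  # Å, intrinsic Born radius

    def __post_init__(self):
        for name in ("charge", "rstar", "epsilon", "gb_radius"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(self.rstar <= 0) or np.any(self.gb_radius <= 0):
            raise ValueError("radii must be positive")
        if not np.all(np.isfinite(self.charge)):
            raise ValueError("charges must be finite")

    def subset(self, indices) -> "ForceFieldParams":
        i = np.asarray(indices, dtype=int)
        return ForceFieldParams(self.charge[i], self.rstar[i],
                                self.epsilon[i], self.gb_radius[i])

    @classmethod
    def from_table(cls, path_or_buffer) -> "ForceFieldParams":
        """Read a whitespace/comma-delimited table with a header line
        ``index name charge rstar epsilon gb_radius`` (order by index)."""
        df = pd.read_csv(path_or_buffer, sep=None, engine="python",
                         comment="#").sort_values("index")
        return cls(df["charge"].to_numpy(), df["rstar"].to_numpy(),
                   df["epsilon"].to_numpy(), df["gb_radius"].to_numpy())

    def to_table(self, names=None) -> str:
        n = len(self.charge)
        names = names if names is not None else [f"A{i+1}" for i in range(n)]
        buf = io.StringIO()
        buf.write("index,name,charge,rstar,epsilon,gb_radius\n")
        for i in range(n):
            buf.write(f"{i},{names[i]},{self.charge[i]},{self.rstar[i]},"
                      f"{self.epsilon[i]},{self.gb_radius[i]}\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# gas-phase terms
# ---------------------------------------------------------------------------

def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.linalg.norm(d, axis=1)


def cross_pairs(group_a, group_b) -> np.ndarray:
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    return np.array(np.meshgrid(a, b)).T.reshape(-1, 2)


def coulomb_energy(coords: np.ndarray, params: ForceFieldParams,
                   pairs: np.ndarray, dielectric: float = 1.0) -> float:
    """Coulomb sum k_e q_i q_j / (eps_r r_ij) over the given atom pairs."""
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return 0.0
    r = _pair_distances(coords, pairs)
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms in a Coulomb pair")
    q = params.charge
    return float(np.sum(K_COULOMB * q[pairs[:, 0]] * q[pairs[:, 1]] /
                        (dielectric * r)))


def lj_energy(coords: np.ndarray, params: ForceFieldParams,
              pairs: np.ndarray) -> float:
    """12-6 Lennard-Jones: eps_ij [ (R/r)^12 - 2 (R/r)^6 ], R = R*_i + R*_j."""
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return 0.0
    r = _pair_distances(coords, pairs)
    if np.any(r < 1e-9):
        raise ValueError("zero distance in a Lennard-Jones pair")
    rmin = params.rstar[pairs[:, 0]] + params.rstar[pairs[:, 1]]
    eps = np.sqrt(params.epsilon[pairs[:, 0]] * params.epsilon[pairs[:, 1]])
    x6 = (rmin / r) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def born_radii(coords: np.ndarray, params: ForceFieldParams,
               offset: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Effective Born radii by Hawkins-Cramer-Truhlar pairwise descreening.

    Each atom's inverse radius starts at the inverse intrinsic radius (less
    ``offset``) and is reduced by the analytic integral of 1/r⁴ over every
    neighbour sphere (scaled by ``scale``).  With no neighbours the effective
    radius equals the intrinsic radius (exact single-sphere limit for the
    default offset of 0).
    """
    rho = params.gb_radius - offset
    if np.any(rho <= 0):
        raise ValueError("intrinsic radius minus offset must stay positive")
    n = coords.shape[0]
    inv = 1.0 / rho.copy()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            sj = scale * rho[j]
            if r >= rho[i] + sj:
                lower = r - sj
            elif r > abs(rho[i] - sj):
                lower = rho[i]
            elif rho[i] < sj:
                lower = sj - r
            else:
                continue  # sphere j fully inside atom i's own radius
            upper = r + sj
            term = 0.5 * (
                1.0 / lower - 1.0 / upper
                + (r / 4.0) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
                + (1.0 / (2.0 * r)) * np.log(lower / upper)
                + (sj ** 2 / (4.0 * r)) * (1.0 / lower ** 2 - 1.0 / upper ** 2)
            )
            inv[i] -= term
        if inv[i] <= 0:
            raise ValueError(f"nonpositive effective Born radius for atom {i}")
    return 1.0 / inv


def f_gb(r: np.ndarray, ri: np.ndarray, rj: np.ndarray) -> np.ndarray:
    rr = ri * rj
    return np.sqrt(r * r + rr * np.exp(-(r * r) / (4.0 * rr)))


def gb_energy(coords: np.ndarray, params: ForceFieldParams,
              solvent_dielectric: float = SOLVENT_DIELECTRIC,
              solute_dielectric: float = SOLUTE_DIELECTRIC,
              radii: np.ndarray | None = None,
              offset: float = 0.0, scale: float = 1.0) -> float:
    """Pairwise generalized-Born polar solvation energy (kcal/mol).

    ``-0.5 (1/eps_in - 1/eps_out) k_e sum over ordered pairs (incl. self
    terms, f_GB(0) = R_i)``.  ``radii`` overrides the HCT effective radii.
    """
    if solvent_dielectric <= 0 or solute_dielectric <= 0:
        raise ValueError("dielectrics must be positive")
    reff = born_radii(coords, params, offset, scale) if radii is None else np.asarray(radii, float)
    if np.any(reff <= 0):
        raise ValueError("Born radii must be positive")
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    f = f_gb(d, reff[:, None], reff[None, :])
    np.fill_diagonal(f, reff)
    q = params.charge
    tau = 1.0 / solute_dielectric - 1.0 / solvent_dielectric
    return float(-0.5 * tau * K_COULOMB * np.sum(np.outer(q, q) / f))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = SASA_PROBE,
         n_points: int = SASA_POINTS) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (per-atom, total), Å²."""
    if probe < 0:
        raise ValueError("probe must be >= 0")
    if n_points < 100:
        raise ValueError("need at least 100 sphere points")
    pts = _sphere_points(n_points)
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = coords.shape[0]
    areas = np.empty(n)
    for i in range(n):
        surface = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i or not accessible.any():
                continue
            if np.linalg.norm(coords[i] - coords[j]) > radii[i] + radii[j]:
                continue
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def nonpolar_energy(delta_sasa: float, gamma: float = GAMMA_SASA,
                    b: float = B_SASA) -> float:
    """Linear SASA model of the nonpolar solvation term: gamma*dSASA + b."""
    return gamma * delta_sasa + b


# ---------------------------------------------------------------------------
# binding-energy decomposition
# ---------------------------------------------------------------------------

TERMS = ("dE_ele", "dE_vdW", "dE_gas", "dG_GB", "dG_nonpolar",
         "dG_solvation", "dG_binding", "dG_binding_no_nonpolar")


@dataclass
class EnergyDecomposition:
    """Per-term MM-GBSA table: per-frame values plus mean ± SD (kcal/mol).

    ``dG_binding`` includes the nonpolar term; ``dG_binding_no_nonpolar`` is
    the gas + polar total only (both conventions are reported).  The solute
    entropy contribution is recorded as not computed.
    """

    per_frame: pd.DataFrame
    gamma: float
    b: float
    t_delta_s: str = "not computed"
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.means:
            self.means = {t: float(self.per_frame[t].mean()) for t in TERMS}
            self.sds = {t: float(self.per_frame[t].std(ddof=0)) for t in TERMS}
        pf = self.per_frame
        for lhs, parts in (("dE_gas", ("dE_vdW", "dE_ele")),
                           ("dG_solvation", ("dG_GB", "dG_nonpolar"))):
            if np.abs(pf[lhs] - sum(pf[p] for p in parts)).max() > _IDENTITY_TOL:
                raise ValueError(f"{lhs} identity violated")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "sd": self.sds})


def binding_energy(traj: Trajectory, receptor: AtomSelection,
                   ligand: AtomSelection, params: ForceFieldParams,
                   frames=None, gamma: float = GAMMA_SASA, b: float = B_SASA,
                   solvent_dielectric: float = SOLVENT_DIELECTRIC,
                   solute_dielectric: float = SOLUTE_DIELECTRIC,
                   probe: float = SASA_PROBE, n_points: int = SASA_POINTS,
                   gb_offset: float = 0.0, gb_scale: float = 1.0
                   ) -> EnergyDecomposition:
    """Single-trajectory MM-GBSA decomposition of receptor-ligand binding.

    Receptor and ligand selections must be disjoint and cover the complex.
    Per frame: the gas terms are receptor-ligand cross sums (internal terms
    cancel between complex and separated species), the polar term is
    GB(complex) - GB(receptor) - GB(ligand) with Born radii recomputed for
    each species, and the nonpolar term is gamma * dSASA + b.
    """
    ri, li = receptor.indices, ligand.indices
    if np.intersect1d(ri, li).size:
        raise SelectionError("receptor and ligand selections overlap")
    if len(ri) + len(li) != traj.n_atoms:
        raise SelectionError(
            f"selections cover {len(ri) + len(li)} of {traj.n_atoms} atoms; "
            "receptor + ligand must cover the complex")
    frames = range(traj.n_frames) if frames is None else frames
    pairs = cross_pairs(ri, li)
    p_rec, p_lig = params.subset(ri), params.subset(li)
    rows = []
    for f in frames:
        x = traj.coords[f]
        e_ele = coulomb_energy(x, params, pairs, dielectric=solute_dielectric)
        e_vdw = lj_energy(x, params, pairs)
        gb_c = gb_energy(x, params, solvent_dielectric, solute_dielectric,
                         offset=gb_offset, scale=gb_scale)
        gb_r = gb_energy(x[ri], p_rec, solvent_dielectric, solute_dielectric,
                         offset=gb_offset, scale=gb_scale)
        gb_l = gb_energy(x[li], p_lig, solvent_dielectric, solute_dielectric,
                         offset=gb_offset, scale=gb_scale)
        d_gb = gb_c - gb_r - gb_l
        radii_all = params.gb_radius
        _, s_c = sasa(x, radii_all, probe, n_points)
        _, s_r = sasa(x[ri], radii_all[ri], probe, n_points)
        _, s_l = sasa(x[li], radii_all[li], probe, n_points)
        d_np = nonpolar_energy(s_c - s_r - s_l, gamma, b)
        rows.append({
            "frame": f, "dE_ele": e_ele, "dE_vdW": e_vdw,
            "dE_gas": e_vdw + e_ele, "dG_GB": d_gb, "dG_nonpolar": d_np,
            "dG_solvation": d_gb + d_np,
            "dG_binding": e_vdw + e_ele + d_gb + d_np,
            "dG_binding_no_nonpolar": e_vdw + e_ele + d_gb,
        })
    return EnergyDecomposition(per_frame=pd.DataFrame(rows).set_index("frame"),
                               gamma=gamma, b=b)


def aggregate_and_compare(decomp_a: EnergyDecomposition,
                          decomp_b: EnergyDecomposition) -> pd.DataFrame:
    """Per-term A - B difference table with the total ddG in the last rows."""
    rows = {t: decomp_a.means[t] - decomp_b.means[t] for t in TERMS}
    return pd.DataFrame({"ddG (A - B)": rows})


def total_from_terms(e_ele: float, e_vdw: float, g_gb: float,
                     g_nonpolar: float | None = None) -> float:
    """Sum printed per-term energies into a binding total.

    With ``g_nonpolar`` None the total is the gas + polar convention
    (dE_ele + dE_vdW + dG_GB) used by tables whose printed totals exclude the
    surface-area row; otherwise the nonpolar term is included.
    """
    total = e_ele + e_vdw + g_gb
    return total if g_nonpolar is None else total + g_nonpolar
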