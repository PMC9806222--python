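"""Config-driven orchestration of the full two-state comparison.

One TOML config drives both conformational states so every contrast (RMSD,
PCA/FEL, DCCM, networks, dCNA, solvation, clustering, energetics) is computed
under identical parameters.  The demo configuration generates synthetic
two-substate ensembles for a "reference" and a "perturbed" state (standing in
for ion-bound vs ion-free trajectories), a solvation toy and a host-guest
energetics toy, then runs all stages and writes one machine-readable report.

Stages run in dependency order; a failed stage never silently skips its
dependents — they are reported as blocked.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
import tomllib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import cluster_frames, pairwise_rmsd, representative_structure, \
    compare_representatives
from .dccm import dccm, interdomain_summary, mask_display
from .errors import ConfigError
from .fit import rmsd_series
from .gbsa import ForceFieldParams, aggregate_and_compare, binding_energy
from .network import (community_strengths, contact_persistence,
                      difference_network, girvan_newman, weight_edges)
from .pca import basin_detect, covariance_pca, fel, project
from .solvation import coordination_number, rdf
from .structure_io import select_atoms
from .synthetic import (EnsembleSpec, SolvationToySpec, block_correlation,
                        generate_binding_toy, generate_correlated_ensemble,
                        generate_solvation_toy, generate_two_state_ensemble,
                        make_chain_topology)

DEFAULTS: dict = {
    "run": {"output_dir": "results/pipeline", "seed": 11, "temperature": 300.0},
    "ensemble": {
        "n_residues": 48, "receptor_residues": 32, "n_frames": 400,
        "amplitude": 0.5, "intra_correlation": 0.6,
        "inter_correlation_state_a": -0.2, "inter_correlation_state_b": -0.5,
        "deformation": 8.0, "substate_weight": 0.5,
    },
    "inputs": {  # optional real-data inputs; empty strings mean "synthetic"
        "state_a_topology": "", "state_a_trajectory": "",
        "state_b_topology": "", "state_b_trajectory": "",
    },
    "rmsd": {"discard": 0},
    "pca": {"bins": 16, "basin_depth": 0.5},
    "dccm": {"mask_threshold": 0.4, "anti_cutoff": -0.4},
    "network": {
        "contact_cutoff": 6.0, "persistence_threshold": 0.75,
        "min_community_size": 3, "use_edge_distances": True,
    },
    "solvation": {
        "shell_radius": 2.35, "shell_occupancy": 7, "box": 24.0,
        "bulk_density": 0.0334, "jitter": 0.05, "n_frames": 50,
        "bin_width": 0.05, "r_max": 8.0, "coordination_cutoff": 3.0,
    },
    "cluster": {"cutoff": 1.2, "stride": 5},
    "gbsa": {
        "gamma": 0.0072, "b": 0.0, "solvent_dielectric": 78.5,
        "solute_dielectric": 1.0, "probe": 1.4, "n_points": 240,
        "n_frames": 10,
    },
    "stages": {
        "fit_rmsd": True, "pca_fel": True, "dccm": True, "network": True,
        "dcna": True, "solvation": True, "cluster": True, "gbsa": True,
    },
}

_RANGE_CHECKS = [
    ("run.temperature", lambda v: v > 0, "must be positive"),
    ("ensemble.substate_weight", lambda v: 0 < v < 1, "must be a proper fraction"),
    ("ensemble.amplitude", lambda v: v > 0, "must be positive"),
    ("network.persistence_threshold", lambda v: 0 <= v < 1,
     "must be a fraction in [0, 1)"),
    ("network.contact_cutoff", lambda v: v > 0, "must be positive"),
    ("dccm.mask_threshold", lambda v: 0 <= v <= 1, "must be a fraction"),
    ("solvation.bin_width", lambda v: v > 0, "must be positive"),
    ("gbsa.n_points", lambda v: v >= 100, "needs at least 100 sphere points"),
]


@dataclass
class PipelineConfig:
    values: dict

    def __getitem__(self, dotted: str):
        node = self.values
        for part in dotted.split("."):
            node = node[part]
        return node

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True).encode()).hexdigest()[:16]


def _merge(defaults: dict, user: dict, prefix: str, errors: list) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"unknown key {prefix}{key!r}{suffix}")
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{prefix}{key} must be a table")
                continue
            out[key] = _merge(defaults[key], val, f"{prefix}{key}.", errors)
        else:
            out[key] = val
    return out


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and validate a pipeline TOML config; fill defaults.

    Unknown keys are rejected (with a near-match hint), parameters are range
    checked, and any referenced input files must exist.  All problems are
    reported together in one itemized error.
    """
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict, "rb") as fh:
            user = tomllib.load(fh)
    errors: list[str] = []
    values = _merge(DEFAULTS, user, "", errors)
    cfg = PipelineConfig(values=values)
    for dotted, check, msg in _RANGE_CHECKS:
        try:
            v = cfg[dotted]
        except KeyError:
            continue
        if not check(v):
            errors.append(f"{dotted} = {v!r} {msg}")
    for key, path in values["inputs"].items():
        if path and not Path(path).exists():
            errors.append(f"inputs.{key}: file not found: {path}")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# synthetic study system
# ---------------------------------------------------------------------------

def _state_ensemble(cfg: PipelineConfig, inter: float, seed: int):
    e = cfg.values["ensemble"]
    n = e["n_residues"]
    nr = e["receptor_residues"]
    topo = make_chain_topology(n, {"A": nr, "B": n - nr})
    corr = block_correlation(n, [(0, nr), (nr, n)], e["intra_correlation"], inter)
    ref_a = topo.coord
    ref_b = ref_a.copy()
    ref_b[nr:] += e["deformation"] * np.array([1.0, 0.0, 0.0])
    amps = np.full(n, e["amplitude"])
    spec_a = EnsembleSpec(ref_a, corr, amps, e["n_frames"], seed)
    spec_b = EnsembleSpec(ref_b, corr, amps, e["n_frames"], seed + 1)
    traj, labels = generate_two_state_ensemble(spec_a, spec_b,
                                               e["substate_weight"], seed=seed + 2)
    traj.topology.chain = topo.chain
    traj.topology.resid = topo.resid
    return traj, labels, topo


def build_study_system(cfg: PipelineConfig) -> dict:
    """Synthetic two-state study system from the config (deterministic)."""
    seed = cfg["run.seed"]
    e = cfg.values["ensemble"]
    traj_a, labels_a, topo = _state_ensemble(cfg, e["inter_correlation_state_a"], seed)
    traj_b, labels_b, _ = _state_ensemble(cfg, e["inter_correlation_state_b"], seed + 100)
    return {"state_a": (traj_a, labels_a), "state_b": (traj_b, labels_b),
            "topology": topo}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Run all enabled stages and return the structured report."""
    outdir = Path(output_dir or config["run.output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.values["stages"]
    report: dict = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config["run.seed"],
            "version": __version__,
            "config": config.values,
        },
        "stages": {},
        "warnings": [],
    }

    system = build_study_system(config)
    traj_a, labels_a = system["state_a"]
    traj_b, labels_b = system["state_b"]
    topo = system["topology"]
    sel_all = select_atoms(topo, "name CA", label="complex-CA")
    nr = config["ensemble.receptor_residues"]
    idx_a_block = np.arange(nr)
    idx_b_block = np.arange(nr, config["ensemble.n_residues"])

    done: dict[str, bool] = {}

    def run_stage(name, deps, fn):
        if not stages.get(name, True):
            done[name] = False
            return
        if any(not done.get(d, False) for d in deps):
            report["stages"][name] = {"status": "blocked",
                                      "blocked_on": [d for d in deps if not done.get(d)]}
            done[name] = False
            return
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                block = fn()
            for w in wlist:
                report["warnings"].append(f"{name}: {w.message}")
            report["stages"][name] = {"status": "ok", **_round_floats(block)}
            done[name] = True
        except Exception as exc:  # collected, not fatal; dependents blocked
            report["stages"][name] = {"status": "error", "error": str(exc)}
            done[name] = False

    # --- fit/RMSD ---
    def stage_fit():
        out = {}
        ref = topo
        for state, traj in (("state_a", traj_a), ("state_b", traj_b)):
            series = rmsd_series(traj, ref, sel_all, discard=config["rmsd.discard"])
            np.savetxt(outdir / f"rmsd_{state}.tsv",
                       np.column_stack([np.arange(len(series.values)), series.values]),
                       header="frame\trmsd_A", delimiter="\t", comments="")
            out[state] = {"mean": series.mean, "sd": series.sd,
                          "n_frames": int(len(series.values))}
        return out

    # --- PCA/FEL ---
    pca_store = {}

    def stage_pca():
        out = {}
        for state, traj in (("state_a", traj_a), ("state_b", traj_b)):
            model = covariance_pca(traj, sel_all, topo)
            proj = project(traj, model, 2)
            grid = fel(proj, config["run.temperature"], bins=config["pca.bins"])
            basins = basin_detect(grid, config["pca.basin_depth"])
            pca_store[state] = (model, proj)
            np.savetxt(outdir / f"projections_{state}.tsv", proj,
                       header="PC1\tPC2", delimiter="\t", comments="")
            out[state] = {
                "pc1_pc2_variance_fraction":
                    float(model.variance_fractions[:2].sum()),
                "n_basins": len(basins),
                "basins": [{"pc1": b.location[0], "pc2": b.location[1],
                            "depth_kcal_mol": b.depth} for b in basins],
            }
        return out

    # --- DCCM ---
    dccm_store = {}

    def stage_dccm():
        out = {}
        for state, traj in (("state_a", traj_a), ("state_b", traj_b)):
            matrix = dccm(traj, sel_all, topo)
            dccm_store[state] = matrix
            np.savetxt(outdir / f"dccm_{state}.tsv", matrix.correlation,
                       delimiter="\t")
            np.savetxt(outdir / f"dccm_{state}_masked.tsv",
                       mask_display(matrix, config["dccm.mask_threshold"]),
                       delimiter="\t")
            s = interdomain_summary(matrix, idx_a_block, idx_b_block,
                                    config["dccm.anti_cutoff"])
            out[state] = {"interdomain_mean": s.mean_correlation,
                          "fraction_anticorrelated": s.fraction_anticorrelated}
        return out

    # --- network ---
    net_store = {}

    def stage_network():
        out = {}
        for state, traj in (("state_a", traj_a), ("state_b", traj_b)):
            graph = contact_persistence(
                traj, topo, cutoff=config["network.contact_cutoff"],
                threshold=config["network.persistence_threshold"])
            graph = weight_edges(graph, dccm_store[state])
            net_store[state] = graph
            with open(outdir / f"edges_{state}.tsv", "w") as fh:
                fh.write("node_i\tnode_j\tpersistence\tdistance\n")
                for u, v, d in sorted(graph.graph.edges(data=True)):
                    fh.write(f"{u}\t{v}\t{d['persistence']:.4f}\t"
                             f"{d.get('distance', float('nan')):.6f}\n")
            out[state] = {"n_edges": graph.graph.number_of_edges()}
        part = girvan_newman(net_store["state_a"],
                             min_size=config["network.min_community_size"],
                             use_edge_distances=config["network.use_edge_distances"])
        net_store["partition"] = part
        with open(outdir / "communities_state_a.tsv", "w") as fh:
            fh.write("residue\tcommunity\n")
            for node, cid in sorted(part.assignment.items()):
                fh.write(f"{node}\t{cid}\n")
        out["communities"] = {"n": len(part.sizes),
                              "sizes": {str(k): v for k, v in sorted(part.sizes.items())},
                              "modularity": part.modularity}
        return out

    # --- dCNA ---
    def stage_dcna():
        dn = difference_network(net_store["state_a"], net_store["state_b"],
                                net_store["partition"])
        delta = {f"{a}-{b}": v for (a, b), v in dn.delta.items()}
        with open(outdir / "dcna.tsv", "w") as fh:
            fh.write("community_pair\tdelta_strength\n")
            for k, v in delta.items():
                fh.write(f"{k}\t{v:.6f}\n")
        inter = {k: v for k, v in delta.items() if k.split("-")[0] != k.split("-")[1]}
        return {"delta_strengths": delta,
                "net_intercommunity_change": float(sum(inter.values()))}

    # --- solvation ---
    def stage_solvation():
        s = config.values["solvation"]
        box = np.full(3, s["box"])
        spec = SolvationToySpec(box / 2, s["shell_radius"], s["shell_occupancy"],
                                box, s["bulk_density"], s["jitter"],
                                s["n_frames"], config["run.seed"] + 500)
        toy = generate_solvation_toy(spec)
        center = select_atoms(toy.topology, "element CA", label="ion")
        target = select_atoms(toy.topology, "element O", label="water O")
        profile = rdf(toy, center, target, s["bin_width"], s["r_max"])
        np.savetxt(outdir / "rdf.tsv",
                   np.column_stack([profile.bin_centers, profile.g,
                                    profile.n_running]),
                   header="r_A\tg\tn_running", delimiter="\t", comments="")
        cn = coordination_number(profile, s["coordination_cutoff"])
        peak = float(profile.bin_centers[int(np.argmax(profile.g))])
        return {"first_shell_peak_A": peak, "coordination_number": cn,
                "bulk_g_mean": float(profile.g[profile.bin_centers > 6.0].mean())}

    # --- clustering ---
    def stage_cluster():
        out = {}
        reps = {}
        for state, (traj, labels) in (("state_a", (traj_a, labels_a)),
                                      ("state_b", (traj_b, labels_b))):
            matrix, frames = pairwise_rmsd(traj, sel_all,
                                           stride=config["cluster.stride"])
            res = cluster_frames(matrix, config["cluster.cutoff"], frames)
            reps[state] = representative_structure(traj, res)
            true = labels[frames]
            pred = res.labels == res.labels[0]
            ref = true == true[0]
            agreement = float(max(np.mean(pred == ref), np.mean(pred != ref)))
            out[state] = {"n_clusters": res.n_clusters,
                          "populations": {str(k): v for k, v in res.populations.items()},
                          "substate_agreement": agreement}
        out["cross_state_rmsd_A"] = compare_representatives(
            reps["state_a"], reps["state_b"], sel_all)
        return out

    # --- energetics ---
    def stage_gbsa():
        g = config.values["gbsa"]
        out = {}
        decomps = {}
        for state, sep in (("state_a", 4.0), ("state_b", 5.0)):
            toy, q, rs, eps, gr, ri, li = generate_binding_toy(
                g["n_frames"], seed=config["run.seed"] + (0 if state == "state_a" else 1),
                separation=sep)
            params = ForceFieldParams(q, rs, eps, gr)
            rec = select_atoms(toy.topology, "chain R", label="receptor")
            lig = select_atoms(toy.topology, "chain L", label="ligand")
            dec = binding_energy(toy, rec, lig, params, gamma=g["gamma"], b=g["b"],
                                 solvent_dielectric=g["solvent_dielectric"],
                                 solute_dielectric=g["solute_dielectric"],
                                 probe=g["probe"], n_points=g["n_points"])
            decomps[state] = dec
            dec.per_frame.to_csv(outdir / f"gbsa_{state}.tsv", sep="\t")
            out[state] = {"means": dec.means, "sds": dec.sds,
                          "TdS": dec.t_delta_s}
        diff = aggregate_and_compare(decomps["state_a"], decomps["state_b"])
        out["ddG_table"] = diff["ddG (A - B)"].to_dict()
        return out

    run_stage("fit_rmsd", [], stage_fit)
    run_stage("pca_fel", [], stage_pca)
    run_stage("dccm", [], stage_dccm)
    run_stage("network", ["dccm"], stage_network)
    run_stage("dcna", ["network"], stage_dcna)
    run_stage("solvation", [], stage_solvation)
    run_stage("cluster", [], stage_cluster)
    run_stage("gbsa", [], stage_gbsa)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def demo_config(output_dir: str = "results/demo", seed: int = 11) -> PipelineConfig:
    """The shipped synthetic two-state demo configuration."""
    return validate_config({"run": {"output_dir": output_dir, "seed": seed}})
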