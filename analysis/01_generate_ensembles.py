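#!/usr/bin/env python
"""Generate the synthetic study fixtures for the two-state comparison.

Builds both conformational states (two-substate mixtures with prescribed
inter-domain correlation structure) plus the ion-solvation toy, writes them
as PDB topology + DCD trajectories under scratch/fixtures/, and records the
true substate labels.  Later analysis steps read these files back through the
package's own I/O, so the whole pipeline is exercised from on-disk formats.
"""

import json
from pathlib import Path

import numpy as np

import mdensemble as md
from mdensemble.pipeline import build_study_system, validate_config

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "fixtures"


def main():
    cfg = validate_config(ROOT / "configs" / "demo_two_state.toml")
    OUT.mkdir(parents=True, exist_ok=True)
    system = build_study_system(cfg)
    md.write_structure(system["topology"], OUT / "topology.pdb")
    for state in ("state_a", "state_b"):
        traj, labels = system[state]
        md.write_trajectory(traj, OUT / f"{state}.dcd")
        np.savetxt(OUT / f"{state}_labels.txt", labels, fmt="%d")
        print(f"{state}: {traj.n_frames} frames, {traj.n_atoms} Cα atoms, "
              f"substate split {np.bincount(labels).tolist()}")

    s = cfg.values["solvation"]
    box = np.full(3, s["box"])
    spec = md.SolvationToySpec(box / 2, s["shell_radius"], s["shell_occupancy"],
                               box, s["bulk_density"], s["jitter"],
                               s["n_frames"], cfg["run.seed"] + 500)
    toy = md.generate_solvation_toy(spec)
    md.write_structure(toy.topology, OUT / "solvation.pdb")
    md.write_trajectory(toy, OUT / "solvation.dcd")
    print(f"solvation toy: {toy.n_frames} frames, {toy.n_atoms} particles "
          f"(1 ion + {s['shell_occupancy']} shell + "
          f"{toy.metadata['n_bulk']} bulk)")

    (OUT / "manifest.json").write_text(json.dumps(
        {"config_hash": cfg.hash(), "seed": cfg["run.seed"]}, indent=2))
    print(f"fixtures written to {OUT}")


if __name__ == "__main__":
    main()
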