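import warnings

import numpy as np
import pytest

import mdensemble as md

# MDAnalysis DCD reader emits a deprecation notice on every open
warnings.filterwarnings("ignore", message="DCDReader currently makes")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain10():
    return md.make_chain_topology(10)


@pytest.fixture
def two_block_ensemble():
    """12-particle two-block ensemble, inter-block correlation -0.5."""
    n = 12
    corr = md.block_correlation(n, [(0, 6), (6, 12)], intra=0.7, inter=-0.5)
    topo = md.make_chain_topology(n, {"A": 6, "B": 6})
    spec = md.EnsembleSpec(topo.coord, corr, np.full(n, 0.5), 10_000, seed=42)
    traj = md.generate_correlated_ensemble(spec)
    traj.topology.chain = topo.chain
    traj.topology.resid = topo.resid
    return traj


@pytest.fixture
def two_state_mix():
    """Two-substate mixture separated by an internal hinge deformation."""
    ref = md.make_chain_topology(10).coord
    ref_b = ref.copy()
    ref_b[:5] += np.array([6.0, 0.0, 0.0])
    ref_b[5:] -= np.array([6.0, 0.0, 0.0])
    ident = np.eye(10)
    amps = np.full(10, 0.4)
    spec_a = md.EnsembleSpec(ref, ident, amps, 4000, seed=1)
    spec_b = md.EnsembleSpec(ref_b, ident, amps, 4000, seed=2)
    return md.generate_two_state_ensemble(spec_a, spec_b, 0.5)


def make_model(coords, names=None, resnames=None, resids=None, chains=None,
               elements=None, hetero=None, occupancy=None, altloc=None):
    """Hand-rolled StructureModel for small fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return md.StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array(names if names is not None else ["CA"] * n),
        resname=np.array(resnames if resnames is not None else ["ALA"] * n),
        resid=np.array(resids if resids is not None else np.arange(1, n + 1)),
        icode=np.array([""] * n),
        chain=np.array(chains if chains is not None else ["A"] * n),
        element=np.array(elements if elements is not None else ["C"] * n),
        occupancy=np.array(occupancy if occupancy is not None else np.ones(n)),
        altloc=np.array(altloc if altloc is not None else [""] * n),
        hetero=np.array(hetero if hetero is not None else np.zeros(n, bool)),
        coord=coords,
    )
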