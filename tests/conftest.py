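import numpy as np
import pytest

from mslambda import (
    AlchemicalTopology,
    ModelHamiltonian,
    SamplerSettings,
    Site,
    ToySpec,
    make_toy_pair,
)


@pytest.fixture
def one_site_topology():
    return AlchemicalTopology([Site("bp4", ("C", "A"))])


@pytest.fixture
def symmetric_pair():
    """1-site toy with identical well depths in both ensembles."""
    spec = ToySpec(
        native="GGTCAA",
        mutants=("GATCAA",),
        bound_depths={"GGTCAA": 0.0, "GATCAA": 0.0},
        unbound_depths={"GGTCAA": 0.0, "GATCAA": 0.0},
    )
    return make_toy_pair(spec)


@pytest.fixture
def gapped_pair():
    """1-site toy with a 2 kcal/mol bound-ensemble gap."""
    spec = ToySpec(
        native="GGTCAA",
        mutants=("GATCAA",),
        bound_depths={"GGTCAA": 0.0, "GATCAA": 2.0},
        unbound_depths={"GGTCAA": 0.0, "GATCAA": 0.0},
    )
    return make_toy_pair(spec)


@pytest.fixture
def quick_settings():
    return SamplerSettings(n_steps=20_000, seed=3)


def random_hamiltonian(topology: AlchemicalTopology, rng: np.random.Generator):
    """Random dense-but-legal Hamiltonian for oracle comparisons."""
    n = topology.n_coords
    h = rng.normal(0.0, 2.0, n)
    J = np.zeros((n, n))
    for s in range(topology.n_sites):
        for t in range(s + 1, topology.n_sites):
            block = rng.normal(0.0, 1.0, (topology.sites[s].n, topology.sites[t].n))
            J[topology.site_slice(s), topology.site_slice(t)] = block
            J[topology.site_slice(t), topology.site_slice(s)] = block.T
    return ModelHamiltonian(
        topology, env_energy=float(rng.normal(0, 1)), h=h, J=J
    )


def random_topology(rng: np.random.Generator, max_sites: int = 4):
    n_sites = int(rng.integers(1, max_sites + 1))
    sites = []
    for s in range(n_sites):
        n_sub = int(rng.integers(2, 5))
        sites.append(Site(f"s{s}", tuple(f"x{i}" for i in range(n_sub))))
    return AlchemicalTopology(sites)


def random_lambda(topology: AlchemicalTopology, rng: np.random.Generator):
    lam = np.empty(topology.n_coords)
    for s in range(topology.n_sites):
        sl = topology.site_slice(s)
        w = rng.random(topology.sites[s].n) + 1e-3
        lam[sl] = w / w.sum()
    return lam
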