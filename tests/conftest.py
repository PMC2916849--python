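import numpy as np
import pytest

import grnsim as gs
from grnsim import fixtures as fx


@pytest.fixture(scope="session")
def cfg():
    """Standard parameter set (cluster-scale defaults; never run at Z=1e5 here)."""
    return gs.SimulationConfig()


@pytest.fixture(scope="session")
def founder(cfg):
    """One viable founder drawn by the model's own initialization procedure."""
    rng = np.random.default_rng(20260101)
    return gs.make_founder(cfg, rng)


@pytest.fixture(scope="session")
def founder_genotype(founder, cfg):
    return gs.develop_genotype(founder, cfg)


@pytest.fixture()
def fig1_genome():
    return fx.make_fig1_genome()


@pytest.fixture()
def oscillator_genome():
    return fx.make_oscillator_genome()


def random_genome(rng, n_reg=None, n_phen=2, L=8, n=50, max_basal=2):
    """A structurally valid random genome with dense interactions.

    Small motif space relative to gene count gives many realized edges,
    exercising the dynamics far from the sparse founder regime.
    """
    from grnsim.genome import Gene, Genome, PHENOTYPIC, REGULATORY

    n_reg = int(rng.integers(2, 8)) if n_reg is None else n_reg
    genes = []
    for i in range(n_reg):
        genes.append(Gene(
            role=REGULATORY,
            trans_number=int(rng.integers(1, n + 1)),
            basal=int(rng.integers(0, max_basal + 1)),
            cis_numbers=rng.integers(1, n + 1, size=L).astype(np.int64),
            coefficients=rng.uniform(-5, 5, size=L),
            is_receptor=(i == 0),
            label=f"R{i + 1}",
        ))
    for i in range(n_phen):
        genes.append(Gene(
            role=PHENOTYPIC,
            trans_number=int(rng.integers(1, n + 1)),
            basal=int(rng.integers(0, max_basal + 1)),
            cis_numbers=rng.integers(1, n + 1, size=L).astype(np.int64),
            coefficients=rng.uniform(-5, 5, size=L),
            label=f"P{i + 1}",
        ))
    return Genome(genes, L=L, n=n)
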