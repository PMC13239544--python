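import numpy as np
import pytest

from geneclim import synthdata
from geneclim.geo_io import GridSpec


@pytest.fixture(scope="session")
def grid10() -> GridSpec:
    return GridSpec(10, 10, xmin=0.0, ymin=0.0, cellsize=100.0)


@pytest.fixture(scope="session")
def small_study():
    """One shared small synthetic study (3 demes, 300 loci, 12 adaptive)."""
    cfg = synthdata.SimConfig(seed=11, n_loci=300, n_adaptive_loci=12,
                              n_individuals=30, n_pops=3)
    stacks, gm, occ, truth = synthdata.simulate(cfg)
    return cfg, stacks, gm, occ, truth


@pytest.fixture(scope="session")
def two_cluster_study():
    """The 2-cluster Fst 0.15 fixture used for admixture recovery."""
    cfg = synthdata.SimConfig(seed=7, n_loci=600, n_adaptive_loci=0,
                              n_individuals=40, n_pops=2, fst_target=0.15,
                              ibd_strength=0.0, missing_rate=0.02)
    stacks, gm, occ, truth = synthdata.simulate(cfg)
    return cfg, stacks, gm, occ, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
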