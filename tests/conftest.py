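import numpy as np
import pytest

from islandscan import GenotypeMatrix, PopulationMap, SimulationConfig, \
    simulate_split_populations


@pytest.fixture(scope="session")
def two_pop_sim():
    """Small two-population dataset shared by read-only tests."""
    cfg = SimulationConfig(n_populations=2, samples_per_pop=10,
                           contig_length=200_000, split_times=[2000], seed=11)
    geno, sites, truth = simulate_split_populations(cfg)
    return cfg, geno, sites, truth, cfg.population_map()


@pytest.fixture
def random_diploids():
    """Factory: random diploid GenotypeMatrix + popmap, optionally with missing."""

    def make(n_per_pop=8, n_sites=40, missing_rate=0.0, seed=0, n_pops=2):
        rng = np.random.default_rng(seed)
        n = n_per_pop * n_pops
        dos = rng.integers(0, 3, size=(n, n_sites)).astype(np.int16)
        if missing_rate > 0:
            dos[rng.random(dos.shape) < missing_rate] = -1
        ids = [f"p{k}_s{i}" for k in range(n_pops) for i in range(n_per_pop)]
        geno = GenotypeMatrix(dos, ids, np.full(n, 2))
        popmap = PopulationMap({s: f"pop{int(s[1]) + 1}" for s in ids})
        return geno, popmap

    return make
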