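import numpy as np
import pandas as pd
import pytest

from popdemog import coalsim
from popdemog.genotype_io import MISSING, PopulationMap, VariantMatrix


def make_matrix(genotypes, locus_ids=None, sample_ids=None):
    """Build a VariantMatrix from a plain nested list of genotype codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    ns, nv = g.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(ns)]
    locus_ids = locus_ids or [f"L{j}" for j in range(nv)]
    pos_within: dict[str, int] = {}
    positions = []
    for lid in locus_ids:
        pos_within[lid] = pos_within.get(lid, 0) + 1
        positions.append((lid, pos_within[lid]))
    return VariantMatrix(sample_ids, list(locus_ids), positions, g)


def random_matrix(rng, n_samples, n_sites, missing_rate=0.0, n_loci=None):
    """Random genotype matrix; loci assigned round-robin."""
    g = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        g[rng.random(g.shape) < missing_rate] = MISSING
    n_loci = n_loci or max(1, n_sites // 3)
    locus_ids = [f"L{j % n_loci}" for j in range(n_sites)]
    # keep sites of a locus adjacent so positions stay increasing per locus
    order = np.argsort([int(l[1:]) for l in locus_ids], kind="stable")
    return make_matrix(g[:, order], [locus_ids[j] for j in order])


@pytest.fixture
def small_matrix():
    # 4 diploids x 6 sites on 3 loci, no missing data
    return make_matrix(
        [
            [0, 1, 2, 0, 1, 0],
            [1, 1, 0, 0, 2, 0],
            [0, 0, 1, 1, 1, 0],
            [2, 1, 0, 0, 0, 1],
        ],
        locus_ids=["L0", "L0", "L1", "L1", "L2", "L2"],
    )


@pytest.fixture
def two_pop_map():
    q = pd.DataFrame(
        {
            "A": [1.0, 0.9, 0.7, 0.0, 0.2, 0.0],
            "B": [0.0, 0.1, 0.3, 1.0, 0.8, 1.0],
        },
        index=[f"s{i}" for i in range(6)],
    )
    assignments = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    return PopulationMap(assignments, q)


@pytest.fixture(scope="session")
def expansion_dataset():
    """Strong-expansion synthetic dataset (10x growth 0.1 time units ago)."""
    cfg = coalsim.DemographyConfig(
        npops=1, epochs=((0.0, 1.0), (0.1, 0.1)), theta=0.8
    )
    return coalsim.simulate_dataset(
        cfg, n_samples=10, n_loci=150, seed=2024, missing_rate=0.05
    )
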