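import numpy as np
import pandas as pd
import pytest

from olivemap.simcross import CrossConfig, simulate_cross
from olivemap.stshap import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_cross():
    """Error-free 3-chromosome cross with complete truth, shared across tests."""
    cfg = CrossConfig(n_chromosomes=3, female_chrom_lengths=[150.0] * 3,
                      markers_per_chromosome=60, n_offspring=200,
                      contaminant_fraction=0.0, genotyping_error_rate=0.0,
                      dsi_chromosome=2, dsi_position=75.0, seed=101)
    genome, pop = simulate_cross(cfg)
    return cfg, genome, pop


@pytest.fixture(scope="session")
def maternal_only_cross():
    """Single-chromosome cross with purely maternal-testcross markers."""
    cfg = CrossConfig(n_chromosomes=1, female_chrom_lengths=[150.0],
                      markers_per_chromosome=60, n_offspring=200,
                      contaminant_fraction=0.0, genotyping_error_rate=0.0,
                      seg_class_mix=(1.0, 0.0, 0.0), dsi_chromosome=1,
                      dsi_position=75.0, seed=7)
    genome, pop = simulate_cross(cfg)
    return cfg, genome, pop


def inject_testcross_flips(gm, rate, seed):
    """Flip offspring calls within each marker's valid testcross call pair."""
    from olivemap.genocall import GenotypeMatrix

    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    flips = set()
    for mid in gm.marker_ids:
        pair = ("A", "H") if gm.father[mid] == "A" else ("H", "B")
        for ind in gm.individuals:
            if rng.random() < rate:
                cur = calls.at[mid, ind]
                calls.at[mid, ind] = pair[0] if cur == pair[1] else pair[1]
                flips.add((mid, ind))
    return GenotypeMatrix(calls, gm.mother.copy(), gm.father.copy(),
                          gm.seg_class.copy()), flips
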