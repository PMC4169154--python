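import numpy as np
import pandas as pd
import pytest

from mosaicqtl.genome import DiplotypeStateSpace, FounderPanel, MarkerMap


@pytest.fixture(scope="session")
def panel():
    return FounderPanel()


@pytest.fixture(scope="session")
def space(panel):
    return DiplotypeStateSpace(panel)


@pytest.fixture(scope="session")
def small_map():
    """Two small chromosomes, strictly increasing bp and cM."""
    rows = []
    for chrom, n, L_cm, L_bp in [("1", 12, 60.0, 120e6), ("2", 8, 40.0, 80e6)]:
        cm = np.linspace(2.0, L_cm, n)
        bp = np.linspace(2e6, L_bp, n).astype(int)
        for k in range(n):
            rows.append((f"m{chrom}_{k}", chrom, bp[k], cm[k]))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chr", "bp", "cM"]))


@pytest.fixture(scope="session")
def sim_population(small_map, panel):
    """A small outbred cohort with full truth, reused across tests."""
    from mosaicqtl.simulate import BreedingConfig, breed_do

    return breed_do(BreedingConfig(n_pairs=40, n_generations=6, n_final=120),
                    small_map, panel, rng=np.random.default_rng(11))
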