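import numpy as np
import pandas as pd
import pytest

from karyofuse.io import FEATURE_COLUMNS
from karyofuse.simulate import (SimulationConfig, apply_fusions,
                                simulate_ancestral_genome)


def feature_frame(rows):
    """Build a feature table from (chrom, start, end, strand, kind, id,
    parent, phase) tuples, padding the optional fields."""
    full = []
    for r in rows:
        r = list(r)
        r += ["", "", -1][len(r) - 5:]  # default id, parent, phase
        full.append(dict(zip(FEATURE_COLUMNS, r)))
    return pd.DataFrame(full, columns=FEATURE_COLUMNS)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(n_chromosomes=8, n_fusions=2,
                            length_range=(60_000, 300_000),
                            gene_density=2e-4, seed=7)


@pytest.fixture(scope="session")
def tiny_system(tiny_config):
    """One small ancestral genome plus its fused derivative and truth."""
    ancestral, truth = simulate_ancestral_genome(tiny_config)
    derived, truth = apply_fusions(ancestral, tiny_config, truth)
    return ancestral, derived, truth


def rng(seed=0):
    return np.random.default_rng(seed)
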