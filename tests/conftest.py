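import logging

import numpy as np
import pandas as pd
import pytest

from crosspool.simulate import SimConfig, simulate_atlas_counts, simulate_pooled_run

logging.getLogger("crosspool").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def design_meta():
    """The study design: 6 replicates x 2 species x 2 sexes = 24 samples."""
    rows = []
    for rep in range(6):
        for sp in ("A", "B"):
            for sx in ("F", "M"):
                rows.append({"sample": f"r{rep}_{sp}{sx}", "replicate": f"r{rep}",
                             "species": sp, "sex": sx})
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture(scope="session")
def default_pool():
    """One full-size pooled run (20,000 droplets, 9% doublets) with truth."""
    return simulate_pooled_run(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_atlas():
    """Small cluster-structured atlas shared across read-only tests."""
    cfg = SimConfig(seed=7, n_genes=300, n_clusters=5, n_cells_per_sample=150)
    return simulate_atlas_counts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
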