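import numpy as np
import pandas as pd
import pytest

import dosegrade as dg


@pytest.fixture(scope="session")
def small_data():
    """A compact simulated study with genome and gene sets (session-wide)."""
    cfg = dg.SimulationConfig(n_genes=300, rng_seed=42)
    return dg.simulate(cfg)


@pytest.fixture(scope="session")
def small_de(small_data):
    return dg.run_de(small_data.counts, small_data.design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def tiny_design(genotypes=("WT",), doses=(0.0, 1000.0), n_rep=3):
    rows = []
    for g in genotypes:
        for d in doses:
            for r in range(1, n_rep + 1):
                rows.append({"sample_id": f"{g}_d{int(d)}_r{r}", "genotype": g,
                             "dose": float(d), "replicate": r})
    return pd.DataFrame(rows)
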