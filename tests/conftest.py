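import numpy as np
import pandas as pd
import pytest

from noapipe import synthetic_data


@pytest.fixture(scope="session")
def gene_universe() -> pd.DataFrame:
    return synthetic_data.generate_gene_universe(800, seed=11)


@pytest.fixture(scope="session")
def ready_pool(gene_universe) -> np.ndarray:
    """Causal pool drawn from aggregation-compatible genes."""
    ready = synthetic_data.aggregation_ready_genes(gene_universe)
    rng = np.random.default_rng(12)
    return rng.choice(ready.to_numpy(), size=200, replace=False)


@pytest.fixture(scope="session")
def cohort(gene_universe, ready_pool):
    """(individuals, findings, truth) for a mid-sized mixed cohort."""
    return synthetic_data.generate_cohort(
        gene_universe,
        ready_pool,
        n_cases=250,
        n_controls=150,
        consang_fraction=0.1,
        fp_rate=0.06,
        seed=13,
    )
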