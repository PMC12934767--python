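import numpy as np
import pytest

import asaskit as ak


@pytest.fixture(scope="session")
def small_cohort():
    """60 individuals, 4 genes, planted delta_psi = 0.4."""
    spec = ak.CohortSpec(
        n_individuals=60, n_genes=4, delta_psi=0.4, mean_coverage=100,
        overdispersion=0.02, seed=7,
    )
    return ak.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    c = small_cohort
    return ak.call_asas(c.counts, c.genotypes, c.metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
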