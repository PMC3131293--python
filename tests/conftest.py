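import numpy as np
import pytest

from reqtl.preprocess import PairedPhenotype
from reqtl.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A compact two-population study with known truth (60 genes)."""
    return simulate_dataset(
        SimConfig(n_genes=60, n_per_pop=(20, 20), snps_per_window=4, seed=42)
    )


def random_paired(rng, n=30, beta_t=0.0, beta_c=0.0, maf=0.3, sigma_u=1.0, sigma_e=1.0):
    """Draw one paired phenotype + dosage instance from the generative model."""
    x = rng.binomial(2, maf, size=n).astype(float)
    while np.all(x == x[0]) or min(x.sum(), 2 * n - x.sum()) < 2:
        x = rng.binomial(2, maf, size=n).astype(float)
    u = rng.normal(0.0, sigma_u, size=n)
    treated = beta_t * x + u + rng.normal(0.0, sigma_e, size=n)
    control = beta_c * x + u + rng.normal(0.0, sigma_e, size=n)
    return PairedPhenotype(treated, control), x
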