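import numpy as np
import pandas as pd
import pytest

from semgwas import GenotypeMatrix, chain_config, simulate_genotypes, simulate_traits


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def small_panel():
    """A 30 x 50 clean dosage panel."""
    rng = np.random.Generator(np.random.PCG64(7))
    p = rng.uniform(0.1, 0.5, 50)
    dos = rng.binomial(2, p, size=(30, 50)).astype(float)
    markers = pd.DataFrame({"id": [f"m{j}" for j in range(50)],
                            "chrom": ["1"] * 50, "pos": range(1, 51)})
    return GenotypeMatrix(ids=[f"i{k}" for k in range(30)], dosages=dos,
                          markers=markers)


@pytest.fixture(scope="session")
def chain_sim():
    """Strong-coefficient chain simulation used by several modules."""
    cfg = chain_config(n=500, m=300, lambdas=(0.8, -0.6, 0.7), seed=11)
    geno = simulate_genotypes(cfg)
    raw, truth = simulate_traits(geno, cfg)
    return cfg, geno, raw, truth
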