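import numpy as np
import pandas as pd
import pytest

from hetvar import SimConfig, simulate_genotypes
from hetvar.datatypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_family_data():
    """One breed, 15 half-sib families of 20, 300 SNPs."""
    cfg = SimConfig(n_breeds=1, animals_per_breed=300, n_sires_per_breed=15,
                    n_snps=300, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def two_breed_data():
    """Two breeds with distinct frequency draws, half-sib structure."""
    cfg = SimConfig(n_breeds=2, animals_per_breed=250, n_sires_per_breed=12,
                    n_snps=400, seed=23)
    return simulate_genotypes(cfg)


def toy_genotypes(geno, animals=None):
    """Wrap a raw genotype array in a GenotypeMatrix with stub metadata."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    snps = pd.DataFrame({
        "snp": [f"S{i}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(m) + 1,
        "a1": "B",
        "a2": "A",
    })
    return GenotypeMatrix(geno, snps, animals or [f"a{i}" for i in range(n)])
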