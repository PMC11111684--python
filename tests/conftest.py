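import numpy as np
import pandas as pd
import pytest

from retrowas.containers import GenotypeMatrix
from retrowas.synthdata import LDBlockSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """500 samples x 200 SNPs in two moderate-LD blocks."""
    blocks = [
        LDBlockSpec(n_snps=100, maf_range=(0.1, 0.5), rho=0.5, chrom="1", start_bp=1),
        LDBlockSpec(n_snps=100, maf_range=(0.1, 0.5), rho=0.5, chrom="2", start_bp=1),
    ]
    return simulate_genotypes(500, blocks, seed=11)


@pytest.fixture()
def herv_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "start": [1_000, 40_000, 80_000],
            "end": [8_000, 47_000, 87_000],
            "name": ["MER4_A", "MER4_B", "MER4_C"],
            "cls": ["herv"] * 3,
            "family": ["MER4"] * 3,
            "strand": ["+", "-", "+"],
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
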