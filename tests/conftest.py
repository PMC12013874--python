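"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from stimqtl.association import GenotypeMatrix
from stimqtl.simulate import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=200, n_variants=300, n_genes=6, ld_block_size=20,
        ld_within_block=0.9, variant_spacing_bp=1_000, seed=11,
    )


@pytest.fixture(scope="session")
def small_geno(small_config) -> GenotypeMatrix:
    return simulate_genotypes(small_config)


def hand_genotypes(dosages: np.ndarray, chrom="1", start_pos=1000, spacing=100) -> GenotypeMatrix:
    """GenotypeMatrix from an explicit (n_samples, n_variants) array."""
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"hv{j}" for j in range(m)],
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(m),
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)], variants=variants, dosages=dosages
    )
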