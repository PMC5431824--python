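"""Shared fixtures: small seeded populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from dioecy import SimConfig, simulate_population
from dioecy.types import GenotypeMatrix


@pytest.fixture(scope="session")
def clean_population():
    """Error-free population: every SDR marker perfectly sex-linked."""
    cfg = SimConfig(n_individuals=200, n_background_snps=400, n_sdr_snps=12,
                    sdr_error_rate=0.0, recombinant_fraction=0.0,
                    missing_rate=0.0, seed=101)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def noisy_population():
    """Population with mistyping, missing calls and recombinants."""
    cfg = SimConfig(n_individuals=600, n_background_snps=300, n_sdr_snps=12,
                    sdr_error_rate=0.01, recombinant_fraction=0.01,
                    missing_rate=0.02, seed=202)
    return simulate_population(cfg)


def toy_matrix(dosages, sample_prefix="s", chrom="Chr01"):
    """Small GenotypeMatrix from a (samples x snps) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos": np.arange(1, m + 1) * 100,
        "id": [f"snp{j + 1}" for j in range(m)],
        "ref": ["A"] * m,
        "alt": ["C"] * m,
    })
    return GenotypeMatrix(dosages=dosages, snps=snps,
                          samples=[f"{sample_prefix}{i + 1}" for i in range(n)])
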