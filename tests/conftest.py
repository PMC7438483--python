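import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from polyburden import synthetic_data as sd
from polyburden.popfreq import GenotypeMatrix


@pytest.fixture
def two_pop_config():
    return sd.SimConfig(
        n_snps=100,
        n_risk_snps=20,
        seed=42,
        populations=(
            sd.PopulationSpec("POPA", 100, 0.05),
            sd.PopulationSpec("POPB", 100, 0.05),
        ),
    )


@pytest.fixture
def small_genotypes(two_pop_config):
    freqs = sd.population_frequency_table(two_pop_config)
    return sd.simulate_genotypes(freqs, two_pop_config)


def make_matrix(dosages, populations=None, chrom="1", spacing=1000, start=1):
    """Hand-rolled GenotypeMatrix from a dense samples x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = [f"S{i:03d}" for i in range(n)]
    if populations is None:
        populations = ["POP"] * n
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(m)],
            "chrom": chrom,
            "pos": start + np.arange(m) * spacing,
            "ref": "A",
            "alt": "G",
        }
    )
    panel = pd.Series(populations, index=pd.Index(samples, name="sample_id"), name="population")
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples, panel=panel)


@pytest.fixture
def make_genotype_matrix():
    return make_matrix
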