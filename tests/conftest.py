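import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from qtnprofile import (GenomeSpec, MatingDesign, build_founders, gene_drop)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def micro_spec():
    """Tiny genome: 2 chromosomes x 0.5 Morgan x 10 SNP/cM = 1,000 SNP."""
    return GenomeSpec(n_chrom=2, chrom_length=0.5, snps_per_cm=10)


@pytest.fixture(scope="session")
def micro_pool(micro_spec):
    return build_founders(micro_spec, ne=30, burn_in=60, seed=11)


@pytest.fixture(scope="session")
def micro_pop(micro_pool):
    """Small population: 150 base + 5 generations of 100."""
    design = MatingDesign(n_sires=12, n_dams=50, base_size=150, n_generations=5)
    return gene_drop(micro_pool, design, seed=12)


@pytest.fixture()
def trio_pedigree():
    """Sire, dam (both founders) and their child."""
    return pd.DataFrame(
        {"id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
         "sex": [0, 1, 0], "generation": [0, 0, 1]}
    )


def random_pedigree(n, n_founders, seed):
    """A valid random pedigree: founders first, then random earlier parents."""
    rng = np.random.default_rng(seed)
    sire = np.zeros(n, dtype=int)
    dam = np.zeros(n, dtype=int)
    sex = rng.integers(0, 2, size=n)
    sex[:2] = [0, 1]
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == 0) + 1
        females = np.flatnonzero(sex[:i] == 1) + 1
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
    return pd.DataFrame(
        {"id": np.arange(1, n + 1), "sire": sire, "dam": dam, "sex": sex,
         "generation": np.where(np.arange(n) < n_founders, 0, 1)}
    )
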