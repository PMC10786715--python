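import numpy as np
import pandas as pd
import pytest

from hemascan.config import SimulationConfig
from hemascan.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_sim_config():
    return SimulationConfig(n_donors=50, n_variants=40, events_per_sample=500, seed=0)


def make_genotypes(dosages: np.ndarray, chrom="1", positions=None) -> GenotypeMatrix:
    """Wrap a raw dosage array in a GenotypeMatrix with synthetic metadata."""
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(
        dosages=dosages, donors=[f"D{i:04d}" for i in range(n)], variants=variants
    )
    gm.recompute_summaries()
    return gm
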