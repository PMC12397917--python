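import numpy as np
import pandas as pd
import pytest

from milletpop.core import GenotypeMatrix, VARIANT_COLUMNS
from milletpop.simulate import DemographyConfig, simulate_cohort


def make_matrix(G, vclass=None, chrom=None, pos=None, samples=None, GQ=None):
    """GenotypeMatrix from a raw code array (rows = samples)."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": pos if pos is not None else 1 + 100 * np.arange(m),
        "id": [f"v{i}" for i in range(m)],
        "ref": ["A"] * m,
        "alt": ["T"] * m,
        "vclass": vclass if vclass is not None else ["SNP"] * m,
    })[VARIANT_COLUMNS]
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        variants=variants, G=G,
        GQ=None if GQ is None else np.asarray(GQ, dtype=np.float32),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = DemographyConfig(L=600, seed=42)
    return simulate_cohort(cfg, [])
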