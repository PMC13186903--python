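import numpy as np
import pytest

from haplostrat import CohortConfig, simulate_cohort
from haplostrat.io import GenotypeMatrix, SnpMap


@pytest.fixture(scope="session")
def small_cohort():
    """Two-breed cohort small enough for per-test reuse: 1,500 SNPs,
    15+15 references, the default 40-animal four-group design."""
    cfg = CohortConfig(seed=20240917, n_snps=1500, n_ref_a=15, n_ref_b=15)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_map(positions, chrom="chr1", start_id=1):
    positions = list(positions)
    return SnpMap(
        np.array([f"m{start_id + i}" for i in range(len(positions))], dtype=object),
        np.array([chrom] * len(positions), dtype=object),
        np.array(positions, dtype=np.int64),
    )


def make_gm(values, ids=None):
    values = np.asarray(values, dtype=np.int8)
    if ids is None:
        ids = [f"a{i}" for i in range(values.shape[0])]
    return GenotypeMatrix(list(ids), values)
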