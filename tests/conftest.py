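import numpy as np
import pytest

from genosynth.basepop import FounderConfig, simulate_founders
from genosynth.genodata import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_founders():
    """Two well-separated ancestry groups, complete genotypes."""
    cfg = FounderConfig(
        group_sizes={"African": 120, "European": 120},
        n_snps=400,
        fst=0.2,
        maf_range=(0.1, 0.5),
        missing_rate=0.0,
        seed=11,
    )
    return simulate_founders(cfg)


@pytest.fixture
def tiny_matrix():
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        snp_ids=["a", "b"],
        ancestry=np.array(["African", "African", "European"], dtype=object),
        genotypes=np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8),
    )


def random_matrix(rng, n=20, m=50, missing_rate=0.1, labels=("African", "European")):
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        geno[rng.random((n, m)) < missing_rate] = -1
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        ancestry=np.array([labels[i % len(labels)] for i in range(n)], dtype=object),
        genotypes=geno,
    )
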