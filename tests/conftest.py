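import numpy as np
import pytest

from poolgea import PoolSeqMatrix, PopulationSet


@pytest.fixture
def tiny_matrix() -> PoolSeqMatrix:
    """2 SNPs x 2 populations with coverages [[20, 18], [25, 0]]."""
    return PoolSeqMatrix(
        snp_ids=["s1", "s2"],
        chrom=["1", "1"],
        pos=[100, 200],
        ref_count=[[12, 9], [25, 0]],
        alt_count=[[8, 9], [0, 0]],
        pop_ids=["popA", "popB"],
    )


@pytest.fixture
def small_pools() -> PopulationSet:
    return PopulationSet(
        pop_ids=["popA", "popB"], haploid_pool_size=[20, 20]
    )


def make_matrix(ref, alt, chrom=None, pos=None):
    ref = np.asarray(ref)
    n, j = ref.shape
    return PoolSeqMatrix(
        snp_ids=[f"s{i}" for i in range(n)],
        chrom=chrom if chrom is not None else ["1"] * n,
        pos=pos if pos is not None else (np.arange(n) + 1) * 10,
        ref_count=ref,
        alt_count=alt,
        pop_ids=[f"p{j_}" for j_ in range(j)],
    )
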