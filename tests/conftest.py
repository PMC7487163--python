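import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admixscan.io import AncestryCalls, AncestryLabelSet, SnpMap

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def labels3() -> AncestryLabelSet:
    return AncestryLabelSet(("EUR", "NAM", "AFR"))


@pytest.fixture
def snp_map5() -> SnpMap:
    return SnpMap(
        snp_id=[f"rs{i}" for i in range(1, 6)],
        chrom=["1", "1", "1", "2", "2"],
        pos_bp=[100, 200, 300, 50, 150],
        gpos_M=[0.001, 0.002, 0.003, 0.0005, 0.0015],
    )


@pytest.fixture
def tiny_calls(labels3, snp_map5) -> AncestryCalls:
    """4 haplotypes (2 diploids) x 5 SNPs, deterministic."""
    calls = np.array([
        [0, 0, 1, 2, 0],
        [1, 0, 1, 0, 0],
        [0, 1, 1, 1, 2],
        [0, 0, 2, 1, 0],
    ], dtype=np.int8)
    return AncestryCalls(snp_map=snp_map5, labels=labels3, calls=calls,
                         sample_ids=["A", "B"])


def make_iid_calls(rng, p_eur: float, n_hap: int, n_snps: int,
                   labels=("EUR", "NAM")) -> AncestryCalls:
    """Null matrix: each cell EUR with probability p_eur, independently."""
    calls = (rng.random((n_hap, n_snps)) >= p_eur).astype(np.int8)
    snp_map = SnpMap([f"s{i}" for i in range(n_snps)], ["1"] * n_snps,
                     np.arange(1, n_snps + 1) * 10)
    return AncestryCalls(snp_map=snp_map, labels=AncestryLabelSet(tuple(labels)),
                         calls=calls, sample_ids=[f"I{j}" for j in range(n_hap // 2)])
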