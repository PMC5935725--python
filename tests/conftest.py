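import numpy as np
import pytest

from chipquant import GenomeModel, GeneRecord, SignalTrack, SyntheticSpec


@pytest.fixture
def tiny_genome() -> GenomeModel:
    """Two chromosomes, four genes on both strands."""
    return GenomeModel(
        chrom_sizes={"chr1": 10_000, "chr2": 8_000},
        genes=[
            GeneRecord("gA", "chr1", "+", 1_000, 3_000, 1_500),
            GeneRecord("gB", "chr1", "-", 4_000, 6_000, 1_200),
            GeneRecord("gC", "chr2", "+", 500, 2_500, 2_000),
            GeneRecord("gD", "chr2", "-", 3_000, 7_000, 3_000),
        ],
    )


@pytest.fixture
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_chroms=1, chrom_length=200_000, n_genes=20, bin_size=200, seed=11
    )


def make_track(values_by_chrom, bin_size=100, **kw) -> SignalTrack:
    return SignalTrack(
        bin_size=bin_size,
        values={c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()},
        **kw,
    )


def poisson_upper_quantile_oracle(lam: float, p_upper: float) -> int:
    """Smallest k with Poisson CDF(k; lam) >= 1 - p_upper, by direct summation."""
    if lam == 0:
        return 0
    target = 1.0 - p_upper
    term = np.exp(-lam)
    cum = term
    k = 0
    while cum < target:
        k += 1
        term *= lam / k
        cum += term
    return k
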