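import numpy as np
import pytest

from epimem.intervals import GenomicInterval, IntervalSet
from epimem.simulate import SimConfig, simulate_annotation, simulate_peak_landscape


def random_interval_set(rng, n, label="s", n_chroms=2, span=10_000, max_len=300):
    """Random unsorted intervals for oracle comparisons."""
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(label=label, intervals=ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_landscape():
    """One shared synthetic landscape for annotation/concordance tests."""
    cfg = SimConfig(seed=11, n_genes=120, n_promoters=90, n_enhancers=240)
    tss, chrom_sizes = simulate_annotation(cfg)
    land = simulate_peak_landscape(cfg, tss, chrom_sizes)
    return cfg, land
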