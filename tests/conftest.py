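import numpy as np
import pytest

from sweepfunc.panel import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(hap, positions=None, chrom="1", populations=None):
    """Panel from a raw haplotype matrix (rows must be even)."""
    hap = np.asarray(hap, dtype=np.int8)
    n_hap, n_sites = hap.shape
    assert n_hap % 2 == 0
    n_samples = n_hap // 2
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    pops = populations or ["pop0"] * n_samples
    return HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions),
        haplotypes=hap,
        samples=[f"s{i}" for i in range(n_samples)],
        populations=pops,
    )


@pytest.fixture
def random_panel(rng):
    """16 haplotypes x 20 sites, complete, all sites polymorphic."""
    while True:
        hap = (rng.random((16, 20)) < rng.uniform(0.1, 0.9, size=20)).astype(np.int8)
        freq = hap.mean(axis=0)
        if ((freq > 0) & (freq < 1)).all():
            return make_panel(hap, positions=np.sort(
                rng.choice(np.arange(1, 60_001), size=20, replace=False)))


# derandomized hypothesis runs: the suite must be reproducible in CI-less
# environments
try:
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True)
    settings.load_profile("deterministic")
except ImportError:
    pass
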