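import numpy as np
import pytest

from zwmap import simpop as sp


@pytest.fixture(scope="session")
def small_cross():
    """A modest cross reused by read-only tests."""
    cfg = sp.SimConfig(
        chrom_lengths=(400_000, 300_000),
        het_rate_p3=0.002, het_rate_p4=0.002, shared_snp_rate=0.0005,
        w_insert_len=10_000, w_locus=("chr01", 200_000),
        n_f1=80, bulk_size=20, depth=25.0, read_len=100,
        xover_rate=0.5, lability=(0.0, 0.0, 0.0), seed=42)
    return sp.simulate_cross(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
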