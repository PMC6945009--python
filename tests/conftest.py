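import numpy as np
import pytest

from ploidyscan.simulate import SimConfig, simulate

# Scaled-down scenario for unit tests: 3 x 1 Mbp, 600 kb duplication on
# chr02, two window-aligned N-gap stretches.
SMALL_KWARGS = dict(
    chromosomes=[("chr01", 1_000_000), ("chr02", 1_000_000), ("chr03", 1_000_000)],
    duplication=("chr02", 300_000, 900_000, "ref_like"),
    n_gap_intervals=[("chr01", 600_000, 700_000), ("chr03", 200_000, 300_000)],
    n_genes=150,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One deterministic small triploid simulation shared across tests."""
    cfg = SimConfig(seed=7, **SMALL_KWARGS)
    out = simulate(cfg, tmp_path_factory.mktemp("small_sim"))
    return cfg, out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
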