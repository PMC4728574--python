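import numpy as np
import pytest

from viromenet import CommunityConfig, default_taxonomy, simulate_community


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_community():
    """A small error-free, spike-free community with ground truth, shared
    across tests that only read from it."""
    cfg = CommunityConfig(
        seed=11,
        n_genomes=8,
        n_read_pairs=4000,
        contaminant_spike_fraction=0.0,
        error_rate=0.0,
    )
    specs, seqs, contigs, truth, r1, r2 = simulate_community(cfg)
    return {
        "config": cfg,
        "specs": specs,
        "seqs": seqs,
        "contigs": contigs,
        "truth": truth,
        "reads1": r1,
        "reads2": r2,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
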