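import warnings

import pytest

from regshift.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default scale, shared read-only."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature configuration for fast IO/CLI round trips."""
    return SimulationConfig(
        seed=7, n_chroms=1, chrom_length=120_000, n_genes=20, n_tfs=2,
        sites_per_tf=20, n_targets=4, frac_altered_sites=0.25,
        n_replicates=2, n_haplotypes=60, n_variants=100, ld_block_size=5,
        n_causal_loci=1,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(autouse=True)
def _quiet_bias_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*k-mers absent from the bias table.*"
        )
        yield
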