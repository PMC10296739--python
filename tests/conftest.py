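import pytest

from mirtally import SynthConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition paired dataset shared across test modules."""
    return generate_paired_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick-to-generate dataset for structural / I/O tests."""
    cfg = SynthConfig(
        n_mirna=80,
        n_gene=400,
        n_de_up=8,
        n_de_down=2,
        cluster_size=3,
        targets_per_mirna=50.0,
        seed=5,
    )
    return generate_paired_dataset(cfg)
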