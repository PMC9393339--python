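import pytest

from lncfat.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 600-gene / 150-lncRNA, 3v3 synthetic study."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced study for fast per-module tests."""
    cfg = GeneratorConfig(
        seed=7,
        n_coding_genes=120,
        n_lncrnas=40,
        n_planted_pairs=6,
        n_planted_tfs=2,
        targets_per_tf=3,
        n_decoy_tfs=5,
        ppi_core_size=6,
        n_fd_decoys=30,
        n_tissue_specific_lnc=3,
        n_tissue_specific_coding=4,
        n_terms=6,
    )
    return generate_dataset(cfg)
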