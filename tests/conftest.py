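import numpy as np
import pytest

from telomap import GenomeAssembly, SyntheticConfig, make_genome


@pytest.fixture
def tiny_assembly() -> GenomeAssembly:
    """Two chromosomes with handwritten sequences for exact-value checks."""
    return GenomeAssembly(
        {"chrA": 40, "chrB": 20},
        {
            "chrA": "GGCCATATGATCAAAGATCNNNNACGTACGTGGGGCCCCA",
            "chrB": "ATATATATATGGCCGGCCAT",
        },
    )


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """Scaled-down generator config for fast unit tests."""
    return SyntheticConfig(
        seed=11,
        n_chrom=4,
        chrom_length_bp=100_000,
        n_ntbs=8,
        ntbs_margin_bp=25_000,
        n_pairs=200_000,
    )


@pytest.fixture(scope="session")
def small_genome():
    """(assembly, planted) for a small default-condition genome."""
    cfg = SyntheticConfig(
        seed=11,
        n_chrom=4,
        chrom_length_bp=100_000,
        n_ntbs=8,
        ntbs_margin_bp=25_000,
        n_pairs=200_000,
    )
    assembly, planted = make_genome(cfg)
    return cfg, assembly, planted


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
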