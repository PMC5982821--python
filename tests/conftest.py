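import pytest

from temex.annotation import build_resolved_annotation
from temex.synthetic import SyntheticConfig, generate_genome_annotation


@pytest.fixture(scope="session")
def small_config():
    """Compact study conditions reused across module tests."""
    return SyntheticConfig(
        n_chromosomes=2,
        chrom_length_bp=150_000,
        n_genes=20,
        n_te_families=8,
        copies_per_family=3,
        read_depth=5_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    genes, tes, truth = generate_genome_annotation(small_config)
    return genes, tes, truth


@pytest.fixture(scope="session")
def small_resolved(small_annotation):
    genes, tes, _ = small_annotation
    return build_resolved_annotation(genes, tes)
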