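import pytest

from mutforge.catalog import ReferenceGenome
from mutforge.synthetic import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def toy_sg():
    """Default 10 Mb / 4-chromosome synthetic genome with islands and genes."""
    return generate_genome(SyntheticGenomeSpec(seed=11))


@pytest.fixture(scope="session")
def small_sg():
    """2 Mb genome for fast repeated simulations."""
    spec = SyntheticGenomeSpec(
        chrom_lengths={f"chr{i}": 500_000 for i in range(1, 5)},
        n_genes=20,
        gene_length_range=(5_000, 15_000),
        seed=13,
    )
    return generate_genome(spec)


@pytest.fixture()
def tiny_genome():
    return ReferenceGenome({"chr1": "AACGTACGTTGCCA", "chr2": "ACGTAACCGGTT"})
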