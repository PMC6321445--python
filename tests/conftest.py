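import pytest
from hypothesis import HealthCheck, settings

from cubtools.sequence_io import CodingSequence

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_gene(codons, gene_id="g", **kwargs) -> CodingSequence:
    return CodingSequence(gene_id=gene_id, codons=tuple(codons), **kwargs)


@pytest.fixture
def gene_factory():
    return make_gene


@pytest.fixture(scope="session")
def random_genes():
    """200 random synthetic genes (uniform-ish codon usage with varying
    GC3), shared by oracle-equivalence tests."""
    from cubtools.synthetic import GeneratorSpec, generate_genome

    genes = []
    for i, gc3 in enumerate([0.2, 0.35, 0.5, 0.65]):
        genome, _ = generate_genome(
            GeneratorSpec(
                n_genes=50,
                length_mean=250,
                length_sd=120,
                gc3_target=gc3,
                seed=100 + i,
                label=f"rand{i}",
            )
        )
        genes.extend(genome.genes)
    return genes


@pytest.fixture(scope="session")
def small_genome():
    from cubtools.synthetic import GeneratorSpec, generate_genome

    genome, truth = generate_genome(
        GeneratorSpec(n_genes=60, length_mean=200, length_sd=60, seed=7, label="mini")
    )
    return genome, truth
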