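import pytest

from mitopool.synthetic_pool import effect_catalogue, generate_reference


@pytest.fixture(scope="session")
def paper_scale_genome():
    """Full-size synthetic mitogenome (16,615 bp, 13 protein genes)."""
    return generate_reference(length=16615, n_cds=13, seed=1)


@pytest.fixture(scope="session")
def catalogue(paper_scale_genome):
    reference, annotation = paper_scale_genome
    return effect_catalogue(reference, annotation)


@pytest.fixture(scope="session")
def small_genome():
    """Small genome for fast per-operation tests."""
    return generate_reference(length=4000, n_cds=3, seed=11)
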