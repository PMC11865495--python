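import pytest

from centrokit.simulate import GenomeSpec, build_toy_genome


@pytest.fixture(scope="session")
def small_genome_spec():
    return GenomeSpec(
        segments=[
            ("arm", 5000),
            ("ct", 2000),
            ("hor", 10),
            ("hsat1", 1000),
            ("ct", 1500),
            ("arm", 4000),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_genome_spec):
    return build_toy_genome(small_genome_spec)


@pytest.fixture(scope="session")
def acceptance_genome():
    """~60 kb genome with one 100-monomer HOR array, for recovery tests."""
    spec = GenomeSpec(
        segments=[
            ("arm", 15000),
            ("ct", 5000),
            ("hor", 100),
            ("hsat1", 5000),
            ("ct", 5000),
            ("arm", 15000),
        ],
        seed=7,
    )
    return build_toy_genome(spec)
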