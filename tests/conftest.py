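import pytest

from wrkyscan.io_formats import load_family_table
from wrkyscan.synthetic_data import (
    GeneratorConfig,
    generate_genome,
    generate_reference_panel,
)


@pytest.fixture(scope="session")
def family_rows():
    """The packaged 85-gene characterization table."""
    return load_family_table()


@pytest.fixture(scope="session")
def default_genome():
    """Synthetic genome at the default (full family-sized) conditions."""
    return generate_genome(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_panel():
    return generate_reference_panel(GeneratorConfig(seed=1))


def small_config(seed: int = 7) -> GeneratorConfig:
    """A down-scaled generator plan for fast unit tests."""
    return GeneratorConfig(
        seed=seed,
        n_chromosomes=5,
        group_counts={"I": 4, "IIa": 2, "IIb": 2, "IIc": 4, "IId": 2, "IIe": 3, "III": 3},
        variant_plan={"WRKYGKK": 1},
        cluster_plan=[("chr2", 3), ("chr4", 2)],
        segmental_pairs={"I": 1, "IIc": 1, "III": 1},
        tandem_pairs={"IIe": 1},
        n_unplaced=1,
    )


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(small_config())


@pytest.fixture(scope="session")
def small_genome_dir(small_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_genome")
    paths = small_genome.write(outdir)
    return paths
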