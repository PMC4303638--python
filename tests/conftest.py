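import pytest

from cobscreen.catalog import default_catalog
from cobscreen.pipeline import make_demo
from cobscreen.simulate import (
    default_archetypes,
    generate_genomes,
    generate_metagenome_hits,
    noiseless_design,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def genome_fixture():
    """Annotation table + truth for the three packaged genome archetypes."""
    return generate_genomes(default_archetypes(), seed=7)


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """The default 60-sample synthetic study (3 ecotypes, links, noise)."""
    return make_demo(seed=42, outdir=tmp_path_factory.mktemp("demo"))


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Small loss-free study: downstream counts must equal truth exactly."""
    design = noiseless_design(n_samples=3, hits_per_sample=300.0, undersampled=1)
    return generate_metagenome_hits(
        design, seed=3, outdir=tmp_path_factory.mktemp("noiseless")
    )
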