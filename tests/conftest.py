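import pytest

from indelkit.design_core import design_library
from indelkit.fixtures import random_gene


@pytest.fixture(scope="session")
def small_gene():
    """A 60-codon random ORF used across modules."""
    return random_gene(60, 0.50, seed=1)


@pytest.fixture(scope="session")
def small_design(small_gene):
    """A complete default design for the 60-codon gene."""
    return design_library(small_gene)


@pytest.fixture(scope="session")
def medium_design():
    """A 150-codon design spanning several sublibraries."""
    return design_library(random_gene(150, 0.52, seed=2))
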