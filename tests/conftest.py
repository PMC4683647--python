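import pytest

from gynomap import MITOTYPES, MultilocusGenotype
from gynomap.datasets import (
    load_cross_frame,
    load_cross_table,
    load_parent_panel,
    load_published_genotypes,
    mapping_family_matrix,
    synthetic_ppr_annotation,
)


def genotype(d4: str, d6: str, dx: str, mitotype: str = "F") -> MultilocusGenotype:
    return MultilocusGenotype.from_symbols(d4, d6, dx, cytotype=MITOTYPES[mitotype])


@pytest.fixture(scope="session")
def cross_table():
    return load_cross_table()


@pytest.fixture(scope="session")
def cross_frame():
    return load_cross_frame()


@pytest.fixture(scope="session")
def parent_panel():
    return load_parent_panel()


@pytest.fixture(scope="session")
def published_genotypes():
    return load_published_genotypes()


@pytest.fixture(scope="session")
def mapping_matrix():
    return mapping_family_matrix()


@pytest.fixture(scope="session")
def ppr_annotation():
    return synthetic_ppr_annotation()
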