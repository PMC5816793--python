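import numpy as np
import pytest

from cazyarray.catalog import TargetGene
from cazyarray.simulate import generate_fixture, random_coding_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_gene(gene_id, sequence, family="GH5", taxon="bacteria",
              domain=None, organism="Fibrobacter sim-sp. 1"):
    start, end = domain if domain else (0, len(sequence))
    return TargetGene(
        gene_id=gene_id, protein_accession=f"P_{gene_id}", organism=organism,
        taxon_group=taxon, cazy_family=family, coding_sequence=sequence,
        domain_start=start, domain_end=end,
    )


@pytest.fixture
def small_catalog(rng):
    """Seven distinct random genes across families and taxa."""
    fams = ["GH5", "GH9", "GH10", "GH11", "GH43", "GH48", "CE1"]
    taxa = ["bacteria", "bacteria", "bacteria", "protozoa", "protozoa", "fungi", "fungi"]
    return [
        make_gene(f"g{i}", random_coding_sequence(rng, 300), family=fams[i],
                  taxon=taxa[i], domain=(10, 290), organism=f"Org {i}")
        for i in range(7)
    ]


@pytest.fixture(scope="session")
def two_condition_bundle():
    return generate_fixture("two_condition", seed=7)


@pytest.fixture(scope="session")
def pure_culture_bundle():
    return generate_fixture("pure_culture", seed=11)
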