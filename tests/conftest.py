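import numpy as np
import pytest

from essconserv import GeneticCode, SimulationConfig, generate_panel
from essconserv.align import CodonAlignment


@pytest.fixture(scope="session")
def code11():
    return GeneticCode.from_table_id(11)


@pytest.fixture(scope="session")
def sense_codons(code11):
    return code11.sense_codons


def random_codon_pair_columns(rng, n_codons, sense, p_mutate=0.3):
    """Gap-free codon alignment with a mix of 0/1/2/3-position differences."""
    cols = []
    for _ in range(n_codons):
        a = sense[rng.integers(0, len(sense))]
        if rng.random() < p_mutate:
            b = sense[rng.integers(0, len(sense))]
        else:
            b = a
        cols.append((a, b))
    return CodonAlignment(columns=tuple(cols))


@pytest.fixture
def random_alignment_factory(sense_codons):
    def factory(seed, n_codons=30, p_mutate=0.3):
        rng = np.random.default_rng(seed)
        return random_codon_pair_columns(rng, n_codons, sense_codons, p_mutate)

    return factory


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """A small but complete synthetic panel shared across tests."""
    config = SimulationConfig(
        n_organisms=3,
        genes_per_organism=40,
        codons_per_gene=80,
        pne_fraction=0.1,
        seed=42,
    )
    root = tmp_path_factory.mktemp("panel")
    return generate_panel(config, root)
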