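import numpy as np
import pytest
from hypothesis import settings

from codonramp import CodingGene, RRTTable, gen_rrt_table
from codonramp.genetic_code import SENSE_CODONS

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


def make_rrt(default: float = 1.0, **overrides) -> RRTTable:
    """An RRT table with every sense codon at `default` except overrides."""
    entries = {c: default for c in SENSE_CODONS}
    entries.update(overrides)
    return RRTTable(entries)


def make_gene(sequence: str, gene_id: str = "gene1") -> CodingGene:
    return CodingGene.from_sequence(gene_id, sequence)


@pytest.fixture(scope="session")
def rrt_table() -> RRTTable:
    """Synthetic residence-time table used across the suite."""
    return gen_rrt_table(seed=7)


@pytest.fixture(scope="session")
def uniform_rrt() -> RRTTable:
    return make_rrt(1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240701)
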