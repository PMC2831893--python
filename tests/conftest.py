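import numpy as np
import pytest

from retroclades.codonmodel import CodonModelParams
from retroclades.genetics import STANDARD_CODE
from retroclades.seqio import CodonAlignment
from retroclades.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((A:0.12,B:0.3):0.08,(C:0.2,D:0.05) #1:0.1);")


@pytest.fixture
def random_params(rng):
    pi = rng.dirichlet(np.ones(61))
    return CodonModelParams(kappa=2.5, omega_by_partition={0: 0.2, 1: 0.8}, pi=pi)


def random_codon_alignment(rng, taxa, n_sites):
    """Alignment of uniformly random sense codons (no phylogenetic signal)."""
    sense = STANDARD_CODE.sense_codons
    states = rng.integers(0, 61, size=(len(taxa), n_sites))
    rows = ["".join(sense[s] for s in row) for row in states]
    return CodonAlignment(list(taxa), rows)


@pytest.fixture
def four_taxon_alignment(rng):
    return random_codon_alignment(rng, ["A", "B", "C", "D"], 5)
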