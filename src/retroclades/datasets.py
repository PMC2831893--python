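"""Study-condition fixtures: species trees and scenario defaults.

The mammalian species tree below covers the seven Rap1 ortholog lineages
(human, chimp, macaque, rat, mouse, cow, dog); the retrogene clade
(retro1, retro2) is grafted onto the mouse terminal branch, mirroring the
retrotransposition-then-duplication scenario in which both events postdate
the mouse/rat split.  Branch lengths (expected substitutions per codon)
are fixture choices on the scale typical of mammalian ortholog ORF
alignments; the source study reports none.
"""

from __future__ import annotations

import numpy as np

from .codonmodel import CodonModelParams
from .simulate import graft_retrogene_clade
from .trees import Tree, parse_newick

#: Established species phylogeny: ((rodents, primates), (cow, dog)).
SPECIES_NEWICK = (
    "(((mouse:0.08,rat:0.12):0.25,"
    "((human:0.02,chimp:0.02):0.04,macaca:0.06):0.15):0.05,"
    "(cow:0.18,dog:0.15):0.05);"
)

#: Alternative basal arrangement: ((rodents, (cow, dog)), primates).
SPECIES_NEWICK_BASAL_ALT = (
    "(((mouse:0.08,rat:0.12):0.25,(cow:0.18,dog:0.15):0.10):0.05,"
    "((human:0.02,chimp:0.02):0.04,macaca:0.06):0.15);"
)


def species_tree(alternative_basal: bool = False) -> Tree:
    """The 7-taxon mammalian species tree (two basal arrangements)."""
    return parse_newick(SPECIES_NEWICK_BASAL_ALT if alternative_basal else SPECIES_NEWICK)


def study_tree(
    *,
    alternative_basal: bool = False,
    attach_fraction: float = 0.4,
    dup_delay: float = 0.01,
    tip_length: float = 0.05,
) -> Tree:
    """The 9-taxon tree: species tree + foreground retrogene clade on mouse.

    The short stem before the duplication node reflects the inference that
    the duplication followed shortly after the retrotransposition.
    """
    return graft_retrogene_clade(
        species_tree(alternative_basal),
        "mouse",
        attach_fraction=attach_fraction,
        dup_delay=dup_delay,
        tip_length=tip_length,
    )


def study_params(
    omega1: float = 0.05,
    omega2: float = 0.30,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
) -> CodonModelParams:
    """Default generating parameters: strong purifying selection on the
    orthologs (omega1), moderate constraint on the retrogene clade (omega2).
    """
    return CodonModelParams(
        kappa=kappa,
        omega_by_partition={0: omega1, 1: omega2},
        pi=np.full(61, 1 / 61) if pi is None else pi,
    )
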