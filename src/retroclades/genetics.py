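"""Genetic code tables, codon bookkeeping and ORF translation.

The standard nuclear genetic code is the default throughout the package
(Rap1 is a nuclear gene); an alternative :class:`GeneticCode` can be
injected wherever a ``code`` argument is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: IUPAC nucleotide ambiguity codes -> set of bases.
IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Standard code, amino acids in TCAG codon order (NCBI transl_table=1).
_STANDARD_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if the a<->b nucleotide change is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in PURINES) == (b in PURINES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table together with the induced sense-codon order.

    Attributes
    ----------
    table
        Mapping from the 64 uppercase DNA codons to one-letter amino acids,
        with ``"*"`` for stop.
    sense_codons
        The codons that do not encode stop, in lexicographic (ACGT) order.
        This fixed order indexes every 61-dimensional vector and 61x61
        matrix in the substitution model.
    """

    table: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    codon_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.table)}")
        sense = tuple(sorted(c for c, aa in self.table.items() if aa != "*"))
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "codon_index", {c: i for i, c in enumerate(sense)})

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == "*"))

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == "*"

    def translate_codon(self, codon: str) -> str:
        return self.table[codon]

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        return self.table[codon_a] == self.table[codon_b]


def _make_standard() -> GeneticCode:
    codons = ["".join(p) for p in product(NUCLEOTIDES, repeat=3)]
    return GeneticCode(dict(zip(codons, _STANDARD_AA)))


STANDARD_CODE = _make_standard()


def clean_nucleotide(seq: str) -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet plus gaps."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - set(IUPAC_NT) - {"-", "."}
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return out


def translate_orf(
    seq: str,
    code: GeneticCode = STANDARD_CODE,
    *,
    allow_terminal_stop: bool = True,
) -> str:
    """Translate an in-frame open reading frame to a protein string.

    A terminal stop codon is stripped; an internal stop raises ``ValueError``
    (retrogene ORFs analysed here are intact coding sequences, so an internal
    stop indicates a frame or input error).
    """
    seq = clean_nucleotide(seq)
    if len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not a multiple of 3")
    n_codons = len(seq) // 3
    protein = []
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon not in code.table:
            raise ValueError(f"ambiguous or invalid codon {codon!r} at codon {i + 1}")
        aa = code.table[codon]
        if aa == "*":
            if allow_terminal_stop and i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        protein.append(aa)
    return "".join(protein)
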