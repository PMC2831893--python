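"""FASTA alignment I/O and codon-column filtering.

FASTA reading and writing is delegated to Biopython; this module adds the
codon-aware containers and the complete-case column filter used upstream of
likelihood computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GeneticCode, STANDARD_CODE, clean_nucleotide


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


class CodonAlignment:
    """An aligned set of sequences viewed as columns of fixed-width units.

    ``unit=3`` (default) treats the alignment as codon columns; ``unit=1``
    as plain nucleotide columns.  ``source_mask`` records, for a filtered
    alignment, which original column indices were retained.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: Sequence[str],
        *,
        unit: int = 3,
        source_mask: Sequence[int] | None = None,
    ) -> None:
        taxa = list(taxa)
        rows = [clean_nucleotide(r) for r in rows]
        if len(taxa) != len(rows):
            raise ValueError("taxa and rows must have equal length")
        if not taxa:
            raise ValueError("no records: alignment is empty")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        (length,) = lengths
        if length % unit != 0:
            raise ValueError(
                f"alignment length {length} is not a multiple of the unit size {unit}"
            )
        self.taxa = taxa
        self.rows = rows
        self.unit = unit
        self.n_sites = length // unit
        self.source_mask = (
            tuple(source_mask) if source_mask is not None else tuple(range(self.n_sites))
        )
        if len(self.source_mask) != self.n_sites:
            raise ValueError("source_mask length must equal the number of columns")

    # ------------------------------------------------------------------ access
    def column(self, site: int) -> list[str]:
        """All taxa's states at a (0-based) column."""
        u = self.unit
        return [row[u * site : u * site + u] for row in self.rows]

    def site_units(self, taxon: str) -> list[str]:
        row = self.rows[self.taxa.index(taxon)]
        u = self.unit
        return [row[u * i : u * i + u] for i in range(self.n_sites)]

    def codon_indices(self, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
        """(n_taxa, n_sites) matrix of sense-codon indices; raises if any
        column holds a non-sense state (filter first)."""
        if self.unit != 3:
            raise ValueError("codon indices require a codon-mode alignment")
        idx = np.empty((len(self.taxa), self.n_sites), dtype=np.int64)
        for i, row in enumerate(self.rows):
            for j in range(self.n_sites):
                codon = row[3 * j : 3 * j + 3]
                k = code.codon_index.get(codon)
                if k is None:
                    raise ValueError(
                        f"non-sense codon {codon!r} at column {j} in {self.taxa[i]!r}; "
                        "apply filter_codon_columns first"
                    )
                idx[i, j] = k
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonAlignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.rows == other.rows
            and self.unit == other.unit
        )

    def __repr__(self) -> str:  # pragma: no cover
        kind = "codon" if self.unit == 3 else "nucleotide"
        return f"<CodonAlignment {len(self.taxa)} taxa x {self.n_sites} {kind} columns>"


def load_alignment(path, mode: str = "codon") -> CodonAlignment:
    """Read an aligned FASTA file.

    ``mode="codon"`` requires the alignment length to be divisible by 3 and
    views it as codon columns; ``mode="nucleotide"`` views single columns.
    """
    if mode not in ("codon", "nucleotide"):
        raise ValueError(f"unknown mode {mode!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return CodonAlignment(ids, rows, unit=3 if mode == "codon" else 1)


def write_alignment(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def load_sequences(path) -> list[SequenceRecord]:
    """Read (possibly unaligned) FASTA sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    return [SequenceRecord(r.id, str(r.seq)) for r in records]


def write_sequences(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def filter_codon_columns(
    aln: CodonAlignment,
    *,
    stop_policy: str = "error",
    code: GeneticCode = STANDARD_CODE,
) -> CodonAlignment:
    """Complete-case codon-column filter.

    Drops every codon column that contains a gap or ambiguity character in
    any taxon, so that all retained states are among the 61 sense codons.
    Stop codons raise by default (``stop_policy="error"``) since intact ORF
    alignments should contain none; ``stop_policy="drop"`` removes their
    columns instead.
    """
    if aln.unit != 3:
        raise ValueError("codon-column filtering requires a codon-mode alignment")
    if stop_policy not in ("error", "drop"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    keep: list[int] = []
    for j in range(aln.n_sites):
        column = aln.column(j)
        ok = True
        for taxon, codon in zip(aln.taxa, column):
            if codon not in code.table:
                ok = False  # gap or ambiguity
                break
            if code.is_stop(codon):
                if stop_policy == "error":
                    raise ValueError(
                        f"stop codon {codon} at column {j} in {taxon!r} "
                        "(use stop_policy='drop' to remove such columns)"
                    )
                ok = False
                break
        if ok:
            keep.append(j)
    if not keep:
        raise ValueError("no codon columns remain after filtering")
    rows = [
        "".join(row[3 * j : 3 * j + 3] for j in keep) for row in aln.rows
    ]
    mask = tuple(aln.source_mask[j] for j in keep)
    return CodonAlignment(aln.taxa, rows, unit=3, source_mask=mask)
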