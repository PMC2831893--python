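"""Retrocopy insertion-locus diagnostics.

In-silico PCR, IUPAC restriction digests, target-site-duplication (TSD)
detection, LINE-1 endonuclease target scans, and parent-vs-retrogene ORF
difference calls mapped onto the conserved Ras-family GTPase motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genetics import IUPAC_NT, STANDARD_CODE, GeneticCode, reverse_complement, translate_orf


# --------------------------------------------------------------------- PCR
@dataclass
class Amplicon:
    """A predicted PCR product (primer-inclusive coordinates)."""

    template_id: str
    start: int  # 0-based, first base of the forward primer site
    end: int  # half-open, one past the last base of the reverse primer site
    strand: str
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_exact(template: str, probe: str) -> list[int]:
    hits, pos = [], template.find(probe)
    while pos != -1:
        hits.append(pos)
        pos = template.find(probe, pos + 1)
    return hits


def _find_mismatch(template: str, probe: str, max_mismatch: int, protect_3prime: int = 3) -> list[int]:
    """Probe matches allowing mismatches, but none in the 3'-terminal bases."""
    hits = []
    n, m = len(template), len(probe)
    for pos in range(n - m + 1):
        window = template[pos : pos + m]
        mism = sum(a != b for a, b in zip(window, probe))
        if mism <= max_mismatch and window[m - protect_3prime :] == probe[m - protect_3prime :]:
            hits.append(pos)
    return hits


def in_silico_pcr(
    template,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
) -> Amplicon:
    """Predict the PCR product of a primer pair on a linear template.

    Both primers are given 5'->3'.  The forward primer must match the
    template exactly once and the reverse primer's reverse complement must
    match exactly once downstream of it; the amplicon includes both primer
    sites (so its length reproduces gel-measured product sizes).  Mismatch
    tolerance is opt-in and never allowed in the 3'-terminal 3 nt.
    """
    template_id = getattr(template, "id", "template")
    seq = (template if isinstance(template, str) else template.seq).upper().replace("U", "T")
    fwd = fwd.upper().replace("U", "T")
    rev = rev.upper().replace("U", "T")
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    rev_rc = reverse_complement(rev)
    if max_mismatch == 0:
        fwd_hits = _find_exact(seq, fwd)
        rev_hits = _find_exact(seq, rev_rc)
    else:
        fwd_hits = _find_mismatch(seq, fwd, max_mismatch)
        # for the reverse primer the 3' end maps to the *start* of the
        # reverse-complement site on the plus strand
        rev_hits = [
            pos
            for pos in _find_mismatch(seq[::-1], rev_rc[::-1], max_mismatch)
        ]
        rev_hits = [len(seq) - len(rev_rc) - p for p in rev_hits]
    if not fwd_hits:
        raise ValueError("no forward primer match on the template")
    if not rev_hits:
        raise ValueError("no reverse primer match on the template")
    if len(fwd_hits) > 1 or len(rev_hits) > 1:
        raise ValueError(
            f"ambiguous product: {len(fwd_hits)} forward / {len(rev_hits)} reverse primer sites"
        )
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_rc)
    if end <= start + len(fwd):
        raise ValueError("reverse primer site lies upstream of the forward site")
    return Amplicon(
        template_id=template_id,
        start=start,
        end=end,
        strand="+",
        sequence=seq[start:end],
    )


# ------------------------------------------------------------------ digest
#: Enzyme definitions: IUPAC recognition pattern and cut offset from the
#: pattern start (blunt cutters listed with their single top-strand offset).
ENZYMES: dict[str, tuple[str, int]] = {
    "NlaIV": ("GGNNCC", 3),
    "EcoRV": ("GATATC", 3),
    "AluI": ("AGCT", 2),
    "DraI": ("TTTAAA", 3),
}


@dataclass
class DigestResult:
    """Outcome of a restriction digest of a linear sequence."""

    enzyme: str
    pattern: str
    cut_offset: int
    cut_positions: list[int]  # 0-based positions where the sequence is cut
    fragment_lengths: list[int]  # sorted multiset

    @property
    def n_sites(self) -> int:
        return len(self.cut_positions)


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC nucleotide pattern into a regular expression."""
    parts = []
    for ch in pattern.upper():
        bases = IUPAC_NT.get(ch)
        if bases is None:
            raise ValueError(f"malformed IUPAC pattern character {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def digest_sequence(seq: str, enzyme) -> DigestResult:
    """Digest a linear sequence with a restriction enzyme.

    ``enzyme`` is a name from :data:`ENZYMES` or a ``(name, pattern,
    cut_offset)`` / ``(pattern, cut_offset)`` tuple.  All (including
    overlapping) recognition-site matches are found; fragment lengths are
    the gaps between successive cut positions and always sum to the input
    length.
    """
    if isinstance(enzyme, str):
        if enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {enzyme!r}; add it to ENZYMES")
        name, (pattern, offset) = enzyme, ENZYMES[enzyme]
    elif len(enzyme) == 3:
        name, pattern, offset = enzyme
    else:
        pattern, offset = enzyme
        name = pattern
    if not (0 <= offset <= len(pattern)):
        raise ValueError("cut offset must lie within the recognition pattern")
    seq = seq.upper().replace("U", "T")
    rx = re.compile(f"(?=({iupac_regex(pattern)}))")
    cuts = sorted({m.start() + offset for m in rx.finditer(seq) if 0 < m.start() + offset < len(seq)})
    bounds = [0] + cuts + [len(seq)]
    fragments = sorted(b - a for a, b in zip(bounds[:-1], bounds[1:]))
    return DigestResult(
        enzyme=name,
        pattern=pattern,
        cut_offset=offset,
        cut_positions=cuts,
        fragment_lengths=fragments,
    )


# --------------------------------------------------------------------- TSD
@dataclass
class TsdCall:
    """A detected target-site duplication flanking an insert."""

    repeat: str
    five_prime: tuple[int, int]  # 0-based half-open interval of the 5' copy
    three_prime: tuple[int, int]
    mismatches: int
    en_site: int | None  # cleavage coordinate if an EN motif abuts the 5' copy


def find_tsd(
    locus: str,
    insert_interval: tuple[int, int],
    max_len: int = 30,
    max_mismatch: int = 0,
    min_len: int = 6,
) -> TsdCall | None:
    """Find the direct repeat flanking an insert (the retrotransposition TSD).

    Looks for the longest repeat whose 5' copy ends exactly at the insert's
    5' boundary and whose 3' copy starts exactly at its 3' boundary, within
    the mismatch budget; returns ``None`` when the best repeat is shorter
    than ``min_len``.  If the base run immediately 5' of the repeat ends in
    TTTT (the L1 endonuclease motif), its cleavage coordinate is reported.
    """
    locus = locus.upper()
    start, end = insert_interval
    if not (0 <= start <= end <= len(locus)):
        raise ValueError("insert interval outside the locus")
    limit = min(max_len, start, len(locus) - end)
    best = None
    for k in range(min_len, limit + 1):
        five = locus[start - k : start]
        three = locus[end : end + k]
        mism = sum(a != b for a, b in zip(five, three))
        if mism <= max_mismatch:
            best = (k, mism)
    if best is None:
        return None
    k, mism = best
    en_site = start - k if locus[max(0, start - k - 4) : start - k] == "TTTT" else None
    return TsdCall(
        repeat=locus[start - k : start],
        five_prime=(start - k, start),
        three_prime=(end, end + k),
        mismatches=mism,
        en_site=en_site,
    )


# ---------------------------------------------------------------- EN sites
@dataclass
class EnSite:
    """A LINE-1 endonuclease target site (5'-TTTT/A-3')."""

    position: int  # 0-based cleavage point on the plus strand
    strand: str
    extended: bool  # True when the stricter TTTT/AA form is present


def scan_en_sites(seq: str) -> list[EnSite]:
    """Scan both strands for the L1 endonuclease target 5'-TTTT/A-3'.

    The cleavage point is reported as the plus-strand coordinate of the
    phosphodiester bond between the TTTT run and the following A (for minus
    strand hits, the complementary coordinate).  Sites also matching the
    literature-preferred extended form TTTT/AA are flagged.
    """
    seq = seq.upper().replace("U", "T")
    hits: list[EnSite] = []
    for m in re.finditer(r"(?=TTTTA)", seq):
        pos = m.start() + 4
        hits.append(EnSite(position=pos, strand="+", extended=seq[pos : pos + 2] == "AA"))
    rc = reverse_complement(seq)
    n = len(seq)
    for m in re.finditer(r"(?=TTTTA)", rc):
        pos_rc = m.start() + 4
        hits.append(
            EnSite(position=n - pos_rc, strand="-", extended=rc[pos_rc : pos_rc + 2] == "AA")
        )
    return sorted(hits, key=lambda h: (h.position, h.strand))


# ------------------------------------------------------------ protein diff
#: Conserved Ras-family GTPase motifs (1-based residue intervals, inclusive).
#: G1 is the P-loop / Walker A; the effector domain spans 20-45 with the
#: general recognition motif at 32-40 and specificity regions 20-31 / 41-45.
RAP1_MOTIFS: tuple[tuple[str, int, int], ...] = (
    ("G1/Walker A", 10, 17),
    ("G3", 57, 60),
    ("G4", 116, 119),
    ("effector-recognition", 32, 40),
    ("effector-specificity", 20, 31),
    ("effector-specificity", 41, 45),
    ("G2", 28, 40),
)


@dataclass
class ResidueChange:
    position: int  # 1-based
    from_aa: str
    to_aa: str
    notation: str
    motifs: tuple[str, ...] = ()


@dataclass
class ProteinDiff:
    """Residue-level differences between a parent and a retrogene ORF."""

    changes: list[ResidueChange]

    @property
    def notations(self) -> list[str]:
        return [c.notation for c in self.changes]

    def __len__(self) -> int:
        return len(self.changes)


def annotate_motifs(position: int, motifs=RAP1_MOTIFS) -> tuple[str, ...]:
    """All motif annotations covering a 1-based residue position.

    Overlapping motifs (e.g. the effector general-recognition motif inside
    G2) are all reported, most specific first per the table order.
    """
    seen, out = set(), []
    for name, lo, hi in motifs:
        if lo <= position <= hi and name not in seen:
            seen.add(name)
            out.append(name)
    return tuple(out)


def protein_diff(
    parent_orf: str,
    retro_orf: str,
    *,
    code: GeneticCode = STANDARD_CODE,
    motifs=RAP1_MOTIFS,
) -> ProteinDiff:
    """Positionwise residue differences between two equal-length ORFs.

    Inputs may be nucleotide ORFs (translated first) or protein strings.
    Retrocopies are unspliced full-length copies of their parent mRNA, so
    no alignment is attempted: a length mismatch raises.
    """
    prot_a = _as_protein(parent_orf, code)
    prot_b = _as_protein(retro_orf, code)
    if len(prot_a) != len(prot_b):
        raise ValueError(
            f"protein lengths differ ({len(prot_a)} vs {len(prot_b)}); "
            "align explicitly before diffing"
        )
    changes = [
        ResidueChange(
            position=i + 1,
            from_aa=a,
            to_aa=b,
            notation=f"{a}{i + 1}{b}",
            motifs=annotate_motifs(i + 1, motifs),
        )
        for i, (a, b) in enumerate(zip(prot_a, prot_b))
        if a != b
    ]
    return ProteinDiff(changes=changes)


def _as_protein(seq: str, code: GeneticCode) -> str:
    seq = seq.upper().replace("U", "T")
    if set(seq) <= set("ACGT") and len(seq) % 3 == 0 and len(seq) >= 30:
        return translate_orf(seq, code)
    return seq
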