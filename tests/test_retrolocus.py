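"""In-silico PCR, IUPAC digests, TSD detection, EN-site scans, protein diffs."""

import re

import numpy as np
import pytest

from retroclades.genetics import reverse_complement
from retroclades.retrolocus import (
    annotate_motifs,
    digest_sequence,
    find_tsd,
    in_silico_pcr,
    iupac_regex,
    protein_diff,
    scan_en_sites,
)
from retroclades.simulate import simulate_insertion_locus


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ----------------------------------------------------------------- PCR
def test_pcr_planted_primer_sites(rng):
    """Unique primer sites planted at known offsets are recovered exactly."""
    fwd = "GCGGGATTGTCAATATTTAAAC"
    rev = "GCCATAGAAATCAGTTATCCC"
    for trial in range(10):
        left, inner, right = (
            _random_seq(rng, 150),
            _random_seq(rng, 500),
            _random_seq(rng, 150),
        )
        template = left + fwd + inner + reverse_complement(rev) + right
        if template.count(fwd) != 1 or template.count(reverse_complement(rev)) != 1:
            continue
        amp = in_silico_pcr(template, fwd, rev)
        assert amp.start == 150
        assert amp.end == 150 + len(fwd) + 500 + len(rev)
        assert amp.length == len(fwd) + 500 + len(rev)
        assert amp.sequence.startswith(fwd)
        assert amp.sequence.endswith(reverse_complement(rev))


def test_pcr_idempotent_on_own_amplicon(rng):
    fwd, rev = "ATGGCTAGCTAGCTAGG", "CCTAGGATCGATCGATT"
    template = _random_seq(rng, 100) + fwd + _random_seq(rng, 200) + reverse_complement(rev) + _random_seq(rng, 100)
    amp = in_silico_pcr(template, fwd, rev)
    again = in_silico_pcr(amp.sequence, fwd, rev)
    assert again.sequence == amp.sequence
    assert again.start == 0 and again.end == amp.length


def test_pcr_errors(rng):
    fwd, rev = "ATGGCTAGCTAGCTAGG", "CCTAGGATCGATCGATT"
    with pytest.raises(ValueError, match="no forward"):
        in_silico_pcr(_random_seq(rng, 200), fwd, rev)
    with pytest.raises(ValueError, match="at least 15"):
        in_silico_pcr("ATGC" * 30, "ATG", rev)
    # reverse site upstream of the forward site
    template = reverse_complement(rev) + _random_seq(rng, 50) + fwd + _random_seq(rng, 20)
    with pytest.raises(ValueError, match="upstream"):
        in_silico_pcr(template, fwd, rev)
    # ambiguous: two forward sites
    template2 = fwd + _random_seq(rng, 50) + fwd + _random_seq(rng, 30) + reverse_complement(rev)
    with pytest.raises(ValueError, match="ambiguous"):
        in_silico_pcr(template2, fwd, rev)


# --------------------------------------------------------------- digest
def test_digest_no_site_returns_whole_sequence(rng):
    seq = "AT" * 300  # cannot contain GGNNCC
    res = digest_sequence(seq, "NlaIV")
    assert res.cut_positions == []
    assert res.fragment_lengths == [600]


def test_digest_planted_nlaiv_site():
    """A single GGNNCC site at offset 210 cuts 213/787 (blunt, centre cut)."""
    seq = "A" * 210 + "GGATCC" + "A" * 784
    res = digest_sequence(seq, "NlaIV")
    assert res.cut_positions == [213]
    assert res.fragment_lengths == [213, 787]
    assert sum(res.fragment_lengths) == len(seq)


def test_digest_matches_sliding_window_oracle(rng):
    """Random 10 kb sequences: cuts match a naive IUPAC window scan."""
    pattern, offset = "GGNNCC", 3
    for trial in range(3):
        seq = _random_seq(rng, 10000)
        expected_cuts = sorted(
            {
                i + offset
                for i in range(len(seq) - len(pattern) + 1)
                if re.fullmatch(iupac_regex(pattern), seq[i : i + len(pattern)])
            }
        )
        res = digest_sequence(seq, "NlaIV")
        assert res.cut_positions == expected_cuts
        assert sum(res.fragment_lengths) == len(seq)
        # fragments reproduce the partition between successive cuts
        bounds = [0] + expected_cuts + [len(seq)]
        assert sorted(b - a for a, b in zip(bounds[:-1], bounds[1:])) == res.fragment_lengths


def test_digest_overlapping_sites_counted():
    # AGCTAGCT has AluI sites at 0 and 4 (AGCT, cut offset 2)
    res = digest_sequence("AGCTAGCT", "AluI")
    assert res.cut_positions == [2, 6]
    assert res.fragment_lengths == [2, 2, 4]


def test_digest_malformed_pattern():
    with pytest.raises(ValueError, match="malformed"):
        digest_sequence("ACGT", ("GG!CC", 2))


# ------------------------------------------------------------------ TSD
def test_find_tsd_recovers_planted_repeat(rng):
    for tsd_len in (8, 10, 12, 16):
        for seed in range(10):
            loc = simulate_insertion_locus(80, tsd_len, _random_seq(rng, 300), seed=seed)
            call = find_tsd(loc.sequence, loc.insert_interval)
            assert call is not None
            assert call.repeat == loc.tsd
            assert call.five_prime == loc.tsd5_interval
            assert call.three_prime == loc.tsd3_interval
            assert call.mismatches == 0
            assert call.en_site == loc.en_site  # cleavage abuts the 5' copy


def test_find_tsd_none_cases(rng):
    loc = simulate_insertion_locus(60, 0, _random_seq(rng, 100), seed=0)
    assert find_tsd(loc.sequence, loc.insert_interval) is None
    with pytest.raises(ValueError, match="outside"):
        find_tsd("ACGT", (2, 10))


def test_find_tsd_mismatch_budget():
    five = "ACGGTCATTGCA"
    three = "ACGGTCATTGCC"  # one mismatch at the last base
    locus = "G" * 20 + five + "T" * 30 + three + "C" * 20
    interval = (20 + 12, 20 + 12 + 30)
    assert find_tsd(locus, interval, max_mismatch=0) is None
    call = find_tsd(locus, interval, max_mismatch=1)
    assert call is not None and call.mismatches == 1 and len(call.repeat) == 12


# ------------------------------------------------------------- EN sites
def test_en_site_reconstructed_insertion_example():
    """The reconstructed pre-insertion site has one cleavage point between
    the TTTT run and the following A."""
    hits = scan_en_sites("ctcaatcctaTTTTAtgaaatccat")
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1 and plus[0].position == 14
    assert plus[0].extended is False  # TTTT/At..., not TTTT/AA


def test_en_scan_empty_when_absent():
    assert scan_en_sites("GCGCGCGCGC") == []


def test_en_scan_matches_regex_oracle_both_strands(rng):
    for trial in range(5):
        seq = _random_seq(rng, 2000)
        hits = scan_en_sites(seq)
        expected_plus = {m.start() + 4 for m in re.finditer(r"(?=TTTTA)", seq)}
        rc = reverse_complement(seq)
        expected_minus = {
            len(seq) - (m.start() + 4) for m in re.finditer(r"(?=TTTTA)", rc)
        }
        assert {h.position for h in hits if h.strand == "+"} == expected_plus
        assert {h.position for h in hits if h.strand == "-"} == expected_minus


def test_en_scan_strand_symmetry(rng):
    seq = _random_seq(rng, 1500)
    hits = scan_en_sites(seq)
    rc_hits = scan_en_sites(reverse_complement(seq))
    mapped = sorted(
        (len(seq) - h.position, "+" if h.strand == "-" else "-") for h in rc_hits
    )
    assert mapped == sorted((h.position, h.strand) for h in hits)


def test_extended_tttt_aa_flag():
    hits = scan_en_sites("GGGTTTTAACCC")
    plus = [h for h in hits if h.strand == "+"]
    assert plus and plus[0].extended is True


# --------------------------------------------------------- protein diff
def _rap1_like(changes: dict[int, str]) -> str:
    """A synthetic 184-residue Rap1-scaffold protein; real Rap1 sequences are
    not bundled, only the motif coordinates are meaningful."""
    base = list("M" + "QSEALKHFRV" * 18 + "KYA")
    base[11] = "G"  # G12 of the P-loop
    base[34] = "T"  # T35 of the effector/switch I region
    base[41] = "K"  # K42 in the specificity region
    base[58] = "A"  # A59 of the G3 motif
    for pos, aa in changes.items():
        base[pos - 1] = aa
    return "".join(base)


def test_protein_diff_identity_is_empty():
    p = _rap1_like({})
    assert len(protein_diff(p, p)) == 0


def test_protein_diff_hrap1b_retro_style():
    """G12R + K42E: P-loop and effector-specificity annotations."""
    parent = _rap1_like({})
    retro = _rap1_like({12: "R", 42: "E"})
    diff = protein_diff(parent, retro)
    assert diff.notations == ["G12R", "K42E"]
    assert "G1/Walker A" in diff.changes[0].motifs
    assert "effector-specificity" in diff.changes[1].motifs


def test_protein_diff_retro2_style_triple():
    """I9L, T35M, L96V-style triple; T35M inside the general recognition
    motif of the effector domain."""
    parent = _rap1_like({9: "I", 96: "L"})
    retro = _rap1_like({9: "L", 35: "M", 96: "V"})
    diff = protein_diff(parent, retro)
    assert diff.notations == ["I9L", "T35M", "L96V"]
    t35 = diff.changes[1]
    assert "effector-recognition" in t35.motifs
    assert diff.changes[2].motifs == ()  # position 96 is outside all motifs


def test_protein_diff_from_nucleotide_orfs():
    parent_nt = "ATGGCTACGGTT" * 10
    retro_nt = list(parent_nt)
    retro_nt[4] = "T"  # GCT -> GTT at codon 2: A2V
    diff = protein_diff(parent_nt, "".join(retro_nt))
    assert diff.notations == ["A2V"]


def test_protein_diff_length_mismatch_raises():
    with pytest.raises(ValueError, match="lengths differ"):
        protein_diff("MABC", "MABCD")


def test_motif_map_boundaries():
    assert annotate_motifs(10) == ("G1/Walker A",)
    assert annotate_motifs(59) == ("G3",)
    assert annotate_motifs(117) == ("G4",)
    assert set(annotate_motifs(35)) == {"effector-recognition", "G2"}
    assert annotate_motifs(25) == ("effector-specificity", "G2") or annotate_motifs(25) == ("effector-specificity",)
    assert annotate_motifs(150) == ()
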