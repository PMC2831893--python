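"""Event-level simulator: determinism, stationarity, omega and CpG effects."""

import numpy as np
import pytest
from scipy.stats import chisquare

from retroclades.codonmodel import CodonModelParams
from retroclades.datasets import study_params, study_tree
from retroclades.genetics import STANDARD_CODE
from retroclades.simulate import (
    SimConfig,
    graft_retrogene_clade,
    simulate_alignment,
    simulate_insertion_locus,
    simulate_retrogene_scenario,
)
from retroclades.trees import parse_newick


TWO_TAXON = parse_newick("(A:0.4,B:0.4);")


def _params(omega=0.5, kappa=2.0, pi=None):
    return CodonModelParams(
        kappa=kappa,
        omega_by_partition={0: omega},
        pi=np.full(61, 1 / 61) if pi is None else pi,
    )


def test_zero_branch_lengths_copy_root():
    tree = parse_newick("(A:0.0,(B:0.0,C:0.0):0.0);")
    aln, truth = simulate_alignment(
        SimConfig(tree=tree, params=_params(), n_codons=50, seed=1)
    )
    assert len(set(aln.rows)) == 1
    assert truth.events == []


def test_same_seed_bitwise_identical_different_seed_not():
    cfg = dict(tree=study_tree(), params=study_params(), n_codons=60)
    a1, t1 = simulate_alignment(SimConfig(seed=5, **cfg))
    a2, t2 = simulate_alignment(SimConfig(seed=5, **cfg))
    a3, _ = simulate_alignment(SimConfig(seed=6, **cfg))
    assert a1.rows == a2.rows and len(t1.events) == len(t2.events)
    assert a1.rows != a3.rows


def test_long_branch_reaches_stationarity():
    """After 20 expected substitutions per codon the leaf distribution is pi."""
    tree = parse_newick("(A:0.0,B:20.0);")
    rng = np.random.default_rng(2)
    pi = rng.dirichlet(np.full(61, 5.0))
    aln, _ = simulate_alignment(
        SimConfig(tree=tree, params=_params(pi=pi), n_codons=8000, seed=2)
    )
    row = aln.rows[aln.taxa.index("B")]
    counts = np.zeros(61)
    for j in range(8000):
        counts[STANDARD_CODE.codon_index[row[3 * j : 3 * j + 3]]] += 1
    stat, p = chisquare(counts, pi * 8000)
    assert p > 0.001


def test_nonsynonymous_share_increases_with_omega():
    """Paired replicates: omega = 1.0 always yields a larger nonsynonymous
    event share than omega = 0.05."""
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        shares = []
        for omega in (0.05, 1.0):
            _, truth = simulate_alignment(
                SimConfig(tree=TWO_TAXON, params=_params(omega), n_codons=300, seed=1000 + rep)
            )
            nonsyn = sum(not e.synonymous for e in truth.events)
            shares.append(nonsyn / max(1, len(truth.events)))
        if shares[1] > shares[0]:
            wins += 1
    assert wins >= n_rep - 1


def test_truth_counts_match_node_state_differences():
    """Branch event counts agree with direct comparison of the stored
    parent/child node sequences (every event is a real change)."""
    aln, truth = simulate_alignment(
        SimConfig(tree=study_tree(), params=study_params(), n_codons=100, seed=8)
    )
    by_branch = truth.branch_counts()
    for node in truth.tree.postorder():
        if node.parent is None:
            continue
        parent_seq = truth.node_states[node.parent.name]
        child_seq = truth.node_states[node.name]
        observed_diff = sum(a != b for a, b in zip(parent_seq, child_seq))
        n_events = by_branch.get(node.name, {}).get("total", 0)
        # events can revert/overwrite, so the net difference never exceeds them
        assert observed_diff <= n_events


def test_cpg_bias_noop_when_one():
    cfg = dict(tree=TWO_TAXON, params=_params(), n_codons=200)
    a1, t1 = simulate_alignment(SimConfig(seed=3, cpg_bias=1.0, **cfg))
    a2, t2 = simulate_alignment(SimConfig(seed=3, **cfg))
    assert a1.rows == a2.rows
    assert [e.to_codon for e in t1.events] == [e.to_codon for e in t2.events]


def test_cpg_bias_enriches_cpg_context_events():
    """cpg_bias = 20 increases the CpG-context substitution fraction over the
    unbiased control in nearly all paired replicates."""
    wins, n_rep = 0, 15
    for rep in range(n_rep):
        fracs = []
        for bias in (1.0, 20.0):
            _, truth = simulate_alignment(
                SimConfig(
                    tree=TWO_TAXON,
                    params=_params(),
                    n_codons=250,
                    seed=500 + rep,
                    cpg_bias=bias,
                )
            )
            flagged = sum(e.cpg_context for e in truth.events)
            fracs.append(flagged / max(1, len(truth.events)))
        if fracs[1] > fracs[0]:
            wins += 1
    assert wins >= n_rep - 2


def test_retrogene_scenario_grafts_foreground_clade():
    species = parse_newick("((mouse:0.1,rat:0.15):0.1,(cow:0.2,dog:0.2):0.05);")
    tree, aln, truth = simulate_retrogene_scenario(
        species, "mouse", dup_delay=0.01, cfg_params=study_params(), n_codons=50, seed=4
    )
    assert set(tree.leaf_names()) == {"mouse", "rat", "cow", "dog", "retro1", "retro2"}
    fg = {n.name for n in tree.branches() if n.partition == 1}
    assert "retro1" in fg and "retro2" in fg
    assert truth.scenario_events[0][0] == "retrotransposition"
    # total length is preserved plus stem + two tips
    assert tree.total_length() == pytest.approx(
        species.total_length() + 0.01 + 2 * 0.05, abs=1e-12
    )


def test_zero_length_graft_copies_parent_state():
    species = parse_newick("((mouse:0.1,rat:0.15):0.1,(cow:0.2,dog:0.2):0.05);")
    tree, aln, truth = simulate_retrogene_scenario(
        species,
        "mouse",
        dup_delay=0.0,
        cfg_params=study_params(),
        n_codons=40,
        seed=5,
        tip_length=0.0,
    )
    r1 = aln.rows[aln.taxa.index("retro1")]
    r2 = aln.rows[aln.taxa.index("retro2")]
    assert r1 == r2  # no time to diverge after the duplication


def test_insertion_locus_geometry():
    loc = simulate_insertion_locus(80, 12, "ACGTACGTACGT" * 10, seed=7)
    start, end = loc.insert_interval
    assert loc.sequence[start:end] == "ACGTACGTACGT" * 10
    t5a, t5b = loc.tsd5_interval
    t3a, t3b = loc.tsd3_interval
    assert loc.sequence[t5a:t5b] == loc.sequence[t3a:t3b] == loc.tsd
    # EN motif: TTTT immediately 5' of the cleavage point, A right after
    assert loc.sequence[loc.en_site - 4 : loc.en_site] == "TTTT"
    assert loc.sequence[loc.en_site] == "A"
    assert loc.tsd5_interval[0] == loc.en_site  # TSD abuts the cleavage site


def test_insertion_locus_zero_tsd_and_errors():
    loc = simulate_insertion_locus(40, 0, "GGGCCC", seed=1)
    assert loc.tsd == ""
    assert loc.tsd5_interval[0] == loc.tsd5_interval[1]
    with pytest.raises(ValueError, match="non-empty"):
        simulate_insertion_locus(40, 5, "", seed=1)
    with pytest.raises(ValueError, match="flank too short"):
        simulate_insertion_locus(5, 10, "AAA", seed=1)


def test_cpg_bias_below_one_rejected():
    with pytest.raises(ValueError, match="cpg_bias"):
        SimConfig(tree=TWO_TAXON, params=_params(), n_codons=10, seed=0, cpg_bias=0.5)
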