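"""Maximum-parsimony reconstruction, substitution classes, CpG annotation."""

import itertools

import numpy as np
import pytest

from retroclades.ancestral import annotate_cpg, classify_substitutions, fitch_reconstruct
from retroclades.genetics import STANDARD_CODE
from retroclades.seqio import CodonAlignment
from retroclades.simulate import SimConfig, simulate_alignment
from retroclades.codonmodel import CodonModelParams
from retroclades.trees import parse_newick

from conftest import random_codon_alignment


def brute_force_min_changes(tree, leaf_state):
    """Minimum single-character changes by exhaustive assignment over the
    observed-state alphabet at every internal node."""
    alphabet = sorted(set(leaf_state.values()))
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for assign in itertools.product(alphabet, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        for leaf in tree.leaves():
            state[id(leaf)] = leaf_state[leaf.name]
        changes = sum(
            state[id(n)] != state[id(n.parent)] for n in tree.branches()
        )
        best = changes if best is None else min(best, changes)
    return best


def test_invariant_site_has_no_changes():
    tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    aln = CodonAlignment(["a", "b", "c", "d"], ["ATG"] * 4)
    rec = fitch_reconstruct(tree, aln)
    assert rec.n_changes == 0
    assert all(codons == {1: "ATG"} for codons in rec.assignments.values())
    assert rec.events == []


def test_codon59_retro1_case():
    """The codon-59 configuration: one retrocopy carries a Val codon while
    its paralog, the parent gene and the outgroup keep Ala; parsimony places
    a single nonsynonymous change on the retro1 branch."""
    tree = parse_newick(
        "(outgroup:0.1,(mouse:0.05,(retro1:0.02,retro2:0.02):0.01):0.05);"
    )
    aln = CodonAlignment(
        ["outgroup", "mouse", "retro1", "retro2"], ["GCT", "GCT", "GTT", "GCT"]
    )
    rec = classify_substitutions(fitch_reconstruct(tree, aln, [1]))
    assert rec.n_changes == 1
    (event,) = rec.events
    assert event.branch == "retro1"
    assert event.synonymous is False
    assert event.notation == "A1V"
    # every internal node keeps the ancestral Ala codon
    internal_codons = {
        rec.assignments[n.name][1]
        for n in rec.tree.postorder()
        if not n.is_leaf
    }
    assert internal_codons == {"GCT"}
    nwk = rec.annotated_newick()
    assert "retro1[&1=GTT]" in nwk and nwk.endswith(";")


def test_fitch_matches_exhaustive_minimization(rng):
    """Random 5-leaf, 4-site cases: the change count equals brute force."""
    tree = parse_newick("(((a:1,b:1):1,c:1):1,(d:1,e:1):1);")
    for trial in range(25):
        aln = random_codon_alignment(rng, ["a", "b", "c", "d", "e"], 4)
        rec = fitch_reconstruct(tree, aln)
        expected = 0
        for site in range(1, 5):
            for p in range(3):
                leaf_state = {
                    t: aln.site_units(t)[site - 1][p] for t in aln.taxa
                }
                expected += brute_force_min_changes(tree, leaf_state)
        assert rec.n_changes == expected


def test_change_count_invariant_to_leaf_order_and_rooting(rng):
    tree = parse_newick("(((a:1,b:1):1,c:1):1,(d:1,e:1):1);")
    aln = random_codon_alignment(rng, ["a", "b", "c", "d", "e"], 6)
    base = fitch_reconstruct(tree, aln).n_changes
    order = [3, 1, 4, 0, 2]
    shuffled = CodonAlignment(
        [aln.taxa[i] for i in order], [aln.rows[i] for i in order]
    )
    assert fitch_reconstruct(tree, shuffled).n_changes == base
    for leaf in ["a", "c", "e"]:
        rerooted = tree.reroot_on_branch(leaf, 0.5)
        assert fitch_reconstruct(rerooted, aln).n_changes == base


def test_events_connect_parent_and_child_assignments(rng):
    tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    aln = random_codon_alignment(rng, ["a", "b", "c", "d"], 5)
    rec = fitch_reconstruct(tree, aln)
    node_by_name = {n.name: n for n in rec.tree.postorder()}
    for ev in rec.events:
        child = node_by_name[ev.branch]
        assert rec.assignments[child.name][ev.site] == ev.to_codon
        assert rec.assignments[child.parent.name][ev.site] == ev.from_codon


def test_mp_count_never_exceeds_true_event_count():
    """Parsimony is a lower bound on the true number of simulated changes."""
    tree = parse_newick(
        "((a:0.3,b:0.25):0.1,((c:0.2,d:0.3):0.15,e:0.4):0.05);"
    )
    params = CodonModelParams(
        kappa=2.0, omega_by_partition={0: 0.5}, pi=np.full(61, 1 / 61)
    )
    for seed in range(5):
        aln, truth = simulate_alignment(
            SimConfig(tree=tree, params=params, n_codons=120, seed=seed)
        )
        rec = fitch_reconstruct(tree, aln)
        assert rec.n_changes <= len(truth.events)


def test_classification_matches_translate_oracle():
    """All 61 sense codons x single-nucleotide sense neighbours classify
    exactly as an independent translate-and-compare."""
    tree = parse_newick("(x:1,(y:1,z:1):1);")
    checked = 0
    for codon in STANDARD_CODE.sense_codons:
        for p in range(3):
            for base in "ACGT":
                if base == codon[p]:
                    continue
                neighbour = codon[:p] + base + codon[p + 1 :]
                if neighbour not in STANDARD_CODE.codon_index:
                    continue
                aln = CodonAlignment(["x", "y", "z"], [codon, neighbour, neighbour])
                rec = classify_substitutions(fitch_reconstruct(tree, aln))
                aa_a = STANDARD_CODE.table[codon]
                aa_b = STANDARD_CODE.table[neighbour]
                for ev in rec.events:
                    assert ev.synonymous == (aa_a == aa_b)
                checked += 1
    assert checked > 400


@pytest.mark.parametrize(
    "codons,notation,synonymous",
    [
        (("ACG", "ACA"), "T1T", True),  # the synonymous codon-35-type change
        (("ACG", "ATG"), "T1M", False),  # the nonsynonymous T->M change
    ],
)
def test_t35_style_notation(codons, notation, synonymous):
    tree = parse_newick("(x1:1,x2:1,(y:1,z:1):1);")
    aln = CodonAlignment(
        ["x1", "x2", "y", "z"], [codons[0], codons[0], codons[1], codons[1]]
    )
    rec = classify_substitutions(fitch_reconstruct(tree, aln))
    (event,) = rec.events
    assert event.notation == notation and event.synonymous == synonymous


OUTGROUP_TREE = parse_newick("(x1:1,x2:1,(y:1,z:1):1);")


def _quartet(anc, derived):
    return CodonAlignment(["x1", "x2", "y", "z"], [anc, anc, derived, derived])


def test_cpg_annotation_rules():
    # ACG -> ATG with following G: a C->T deamination on the CpG
    rec = annotate_cpg(
        classify_substitutions(
            fitch_reconstruct(OUTGROUP_TREE, _quartet("ACGGGG", "ATGGGG"))
        )
    )
    flagged = [e for e in rec.events if e.notation == "T1M"]
    assert flagged and flagged[0].cpg_flag is True
    # A->G never flags regardless of context
    rec2 = annotate_cpg(
        classify_substitutions(
            fitch_reconstruct(OUTGROUP_TREE, _quartet("CAAGGG", "CAGGGG"))
        )
    )
    assert all(e.cpg_flag is False for e in rec2.events)
    # G->A with preceding C flags on the opposite strand
    rec3 = annotate_cpg(
        classify_substitutions(
            fitch_reconstruct(OUTGROUP_TREE, _quartet("ACGAAA", "ACAAAA"))
        )
    )
    (event,) = rec3.events
    assert event.cpg_flag is True


def test_cpg_edge_context_is_unknown():
    # C->T at the final base of the sequence: next base unknown
    rec = annotate_cpg(
        classify_substitutions(
            fitch_reconstruct(OUTGROUP_TREE, _quartet("AAC", "AAT"))
        )
    )
    assert rec.events and rec.events[0].cpg_flag is None


def test_cpg_enrichment_detected_on_biased_simulations():
    """CpG-flagged fraction under bias exceeds the unbiased control in most
    paired replicates (annotation applied to the *true* parent contexts)."""
    tree = parse_newick("(A:0.5,B:0.5);")
    params = CodonModelParams(
        kappa=2.0, omega_by_partition={0: 0.6}, pi=np.full(61, 1 / 61)
    )
    wins, n_rep = 0, 10
    for rep in range(n_rep):
        fracs = []
        for bias in (1.0, 20.0):
            aln, truth = simulate_alignment(
                SimConfig(tree=tree, params=params, n_codons=200, seed=900 + rep, cpg_bias=bias)
            )
            rec = classify_substitutions(fitch_reconstruct(truth.tree, aln))
            annotate_cpg(rec, context_seqs=truth.node_states)
            flagged = sum(e.cpg_flag is True for e in rec.events)
            fracs.append(flagged / max(1, len(rec.events)))
        if fracs[1] > fracs[0]:
            wins += 1
    assert wins >= n_rep - 2


def test_missing_tracked_site_raises(rng):
    tree = parse_newick("(a:1,(b:1,c:1):1);")
    aln = random_codon_alignment(rng, ["a", "b", "c"], 3)
    with pytest.raises(ValueError, match="outside alignment"):
        fitch_reconstruct(tree, aln, [7])
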