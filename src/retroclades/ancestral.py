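"""Maximum-parsimony ancestral codons and substitution annotation.

Ancestral states are reconstructed per nucleotide position with the
Hartigan generalization of the Fitch algorithm (exact minimum-change
counts on binary and multifurcating rooted trees); codons at internal
nodes are assembled from the three positions.  Implied substitutions are
placed on the branches where parent and child assignments differ, then
classified as synonymous or nonsynonymous, and optionally flagged when
consistent with deamination of a methylated CpG dinucleotide (C->T with
the next base G, or G->A with the previous base C, in the reconstructed
parent context).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetics import GeneticCode, STANDARD_CODE
from .seqio import CodonAlignment
from .trees import Tree


@dataclass
class SubstitutionEvent:
    """A single-nucleotide substitution implied by the reconstruction."""

    branch: str  # name of the child node below the branch
    site: int  # 1-based codon site
    codon_pos: int  # 1..3 within the codon
    from_nt: str
    to_nt: str
    from_codon: str
    to_codon: str
    synonymous: bool | None = None
    cpg_flag: bool | None = None  # None = unknown (missing/ambiguous context)
    notation: str | None = None  # e.g. "T35M", "T35T"
    produces_stop: bool = False


@dataclass
class MPReconstruction:
    """Result of a maximum-parsimony reconstruction on tracked codon sites."""

    tree: Tree
    sites: list[int]  # 1-based codon sites tracked
    assignments: dict[str, dict[int, str]]  # node name -> site -> codon
    ambiguous: dict[str, dict[int, tuple[frozenset, frozenset, frozenset]]]
    events: list[SubstitutionEvent]
    n_changes: int  # minimum number of single-nucleotide changes

    def events_on(self, branch: str) -> list[SubstitutionEvent]:
        return [e for e in self.events if e.branch == branch]

    def annotated_newick(self) -> str:
        """The reconstruction tree with per-node codon assignments attached
        as Newick comment tags (``[&site=codon,...]``)."""
        def render(node) -> str:
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                out = f"({inner}){node.name}"
            else:
                out = node.name
            codons = self.assignments.get(node.name, {})
            if codons:
                tags = ",".join(f"{s}={codons[s]}" for s in sorted(codons))
                out += f"[&{tags}]"
            if node.length is not None:
                out += f":{node.length:.12g}"
            return out

        return render(self.tree.root) + ";"

    def to_table(self):
        """Events as a pandas DataFrame (branch, site, notation, class, cpg)."""
        import pandas as pd

        rows = [
            {
                "branch": e.branch,
                "site": e.site,
                "codon_pos": e.codon_pos,
                "change": f"{e.from_nt}->{e.to_nt}",
                "from_codon": e.from_codon,
                "to_codon": e.to_codon,
                "class": (
                    None
                    if e.synonymous is None
                    else ("synonymous" if e.synonymous else "nonsynonymous")
                ),
                "notation": e.notation,
                "cpg": e.cpg_flag,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows)


def _hartigan_position(tree: Tree, leaf_state: dict[str, str]):
    """Exact minimum-change reconstruction of one character (Hartigan).

    Returns (assignment: node-name -> state, vsets: node-name -> frozenset,
    n_changes).
    """
    vset: dict[int, frozenset] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            vset[id(node)] = frozenset(leaf_state[node.name])
            continue
        counts: dict[str, int] = {}
        for child in node.children:
            for s in vset[id(child)]:
                counts[s] = counts.get(s, 0) + 1
        kmax = max(counts.values())
        vset[id(node)] = frozenset(s for s, c in counts.items() if c == kmax)
        changes += len(node.children) - kmax
    assignment: dict[str, str] = {}
    for node in tree.preorder():
        states = vset[id(node)]
        if node.parent is None:
            assignment[node.name] = min(states)  # deterministic tie-break
        else:
            parent_state = assignment[node.parent.name]
            assignment[node.name] = (
                parent_state if parent_state in states else min(states)
            )
    vsets = {n.name: vset[id(n)] for n in tree.postorder()}
    return assignment, vsets, changes


def fitch_reconstruct(
    tree: Tree,
    aln: CodonAlignment,
    sites: list[int] | None = None,
    *,
    outgroup: str | None = None,
) -> MPReconstruction:
    """Reconstruct ancestral codons at tracked (1-based) codon sites.

    Each of the three nucleotide positions of a codon is reconstructed
    independently under minimum change; the codon at a node is the triple
    of position states.  Events are emitted for every branch/position where
    the parent and child assignments differ.  ``outgroup`` reroots the tree
    on the branch above the named leaf before reconstruction; otherwise the
    supplied rooting is used.
    """
    if aln.unit != 3:
        raise ValueError("reconstruction requires a codon-mode alignment")
    if sites is None:
        sites = list(range(1, aln.n_sites + 1))
    for s in sites:
        if not (1 <= s <= aln.n_sites):
            raise ValueError(f"tracked site {s} outside alignment (1..{aln.n_sites})")
    work = tree.reroot_on_branch(outgroup) if outgroup is not None else tree.copy()
    # give unnamed internal nodes stable labels
    counter = 0
    for node in work.postorder():
        if node.name is None:
            node.name = f"anc{counter}"
            counter += 1
    missing = set(work.leaf_names()) - set(aln.taxa)
    if missing:
        raise ValueError(f"leaves missing from the alignment: {sorted(missing)}")

    codons_by_taxon = {t: aln.site_units(t) for t in aln.taxa}
    assignments: dict[str, dict[int, str]] = {n.name: {} for n in work.postorder()}
    ambiguous: dict[str, dict[int, tuple]] = {n.name: {} for n in work.postorder()}
    events: list[SubstitutionEvent] = []
    total_changes = 0
    for site in sites:
        pos_assign = []
        pos_vsets = []
        for p in range(3):
            leaf_state = {
                t: codons_by_taxon[t][site - 1][p] for t in work.leaf_names()
            }
            assign, vsets, changes = _hartigan_position(work, leaf_state)
            total_changes += changes
            pos_assign.append(assign)
            pos_vsets.append(vsets)
        for node in work.postorder():
            name = node.name
            assignments[name][site] = "".join(pos_assign[p][name] for p in range(3))
            ambiguous[name][site] = tuple(frozenset(pos_vsets[p][name]) for p in range(3))
        for node in work.postorder():
            if node.parent is None:
                continue
            parent_codon = assignments[node.parent.name][site]
            child_codon = assignments[node.name][site]
            for p in range(3):
                if parent_codon[p] != child_codon[p]:
                    events.append(
                        SubstitutionEvent(
                            branch=node.name,
                            site=site,
                            codon_pos=p + 1,
                            from_nt=parent_codon[p],
                            to_nt=child_codon[p],
                            from_codon=parent_codon,
                            to_codon=child_codon,
                        )
                    )
    return MPReconstruction(
        tree=work,
        sites=list(sites),
        assignments=assignments,
        ambiguous=ambiguous,
        events=events,
        n_changes=total_changes,
    )


def classify_substitutions(
    recon: MPReconstruction, code: GeneticCode = STANDARD_CODE
) -> MPReconstruction:
    """Assign synonymous/nonsynonymous class and residue notation to events.

    Notation uses 1-based residue numbering: nonsynonymous ``T35M``,
    synonymous ``T35T``.  Events whose parent or child codon translates to
    a stop are flagged (``produces_stop``) rather than dropped.
    """
    for ev in recon.events:
        aa_from = code.table.get(ev.from_codon)
        aa_to = code.table.get(ev.to_codon)
        if aa_from is None or aa_to is None:
            raise ValueError(
                f"cannot translate codons {ev.from_codon}/{ev.to_codon}"
            )
        ev.produces_stop = aa_from == "*" or aa_to == "*"
        ev.synonymous = aa_from == aa_to
        ev.notation = f"{aa_from}{ev.site}{aa_to}"
    return recon


def annotate_cpg(
    recon: MPReconstruction,
    context_seqs: dict[str, str] | None = None,
) -> MPReconstruction:
    """Flag events consistent with CpG deamination, using parent context.

    ``context_seqs`` maps node names to full nucleotide sequences (e.g.
    from simulation truth); when omitted, the context is assembled from the
    reconstruction itself, which requires all codon sites to be tracked.
    Events at the sequence edge, or whose neighbouring base is ambiguous in
    the reconstruction, get ``cpg_flag=None`` (unknown) rather than False.
    """
    use_recon = context_seqs is None
    if use_recon:
        n_sites = max(recon.sites)
        if recon.sites != list(range(1, n_sites + 1)):
            raise ValueError(
                "CpG context from the reconstruction needs all codon sites "
                "tracked; pass context_seqs explicitly otherwise"
            )
        context_seqs = {
            name: "".join(recon.assignments[name][s] for s in recon.sites)
            for name in recon.assignments
        }

    def neighbour_ambiguous(node_name: str, abs_pos: int) -> bool:
        if not use_recon:
            return False
        site, p = abs_pos // 3 + 1, abs_pos % 3
        amb = recon.ambiguous.get(node_name, {}).get(site)
        return amb is not None and len(amb[p]) > 1

    node_by_name = {n.name: n for n in recon.tree.postorder()}
    for ev in recon.events:
        parent = node_by_name[ev.branch].parent
        context = context_seqs.get(parent.name)
        if context is None:
            ev.cpg_flag = None
            continue
        abs_pos = 3 * (ev.site - 1) + (ev.codon_pos - 1)
        if ev.from_nt == "C" and ev.to_nt == "T":
            if abs_pos + 1 >= len(context):
                ev.cpg_flag = None
            elif neighbour_ambiguous(parent.name, abs_pos + 1):
                ev.cpg_flag = None
            else:
                ev.cpg_flag = context[abs_pos + 1] == "G"
        elif ev.from_nt == "G" and ev.to_nt == "A":
            if abs_pos - 1 < 0:
                ev.cpg_flag = None
            elif neighbour_ambiguous(parent.name, abs_pos - 1):
                ev.cpg_flag = None
            else:
                ev.cpg_flag = context[abs_pos - 1] == "C"
        else:
            ev.cpg_flag = False
    return recon
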