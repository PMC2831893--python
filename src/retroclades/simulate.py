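"""Synthetic data with ground truth: codon alignments evolved along trees
under the clades model, retrotransposition/duplication scenarios, and
genomic loci with planted retrocopies.

Sequence evolution is simulated event-by-event (Gillespie) rather than by
sampling leaf states from P(t), so that every single-nucleotide
substitution exists as a recorded event with its branch, codon site,
nucleotide change, synonymous/nonsynonymous class and CpG context.  This
event-level truth is what the parsimony-reconstruction and CpG-annotation
stages are validated against.

The optional CpG-deamination overlay multiplies the rate of C->T changes
whose next base is G, and of G->A changes whose previous base is C, by
``cpg_bias`` (context re-evaluated after every event, across codon
boundaries; the bases flanking the ORF are fixed in the configuration).
With ``cpg_bias=1`` the overlay is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codonmodel import CodonModelParams, _structure, build_rate_matrix
from .genetics import GeneticCode, STANDARD_CODE
from .seqio import CodonAlignment
from .trees import Node, Tree


@dataclass
class SimConfig:
    """Configuration for one alignment simulation.

    ``tree`` carries the partition labels that select each branch's omega
    from ``params``; ``n_codons`` is the ORF length in codons.  ``flank5``
    and ``flank3`` are the fixed bases assumed to precede/follow the ORF
    when evaluating CpG context at its edges.
    """

    tree: Tree
    params: CodonModelParams
    n_codons: int
    seed: int
    cpg_bias: float = 1.0
    flank5: str = "T"
    flank3: str = "A"

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.cpg_bias < 1.0:
            raise ValueError("cpg_bias must be >= 1 (it is an overlay multiplier)")


@dataclass
class SubstitutionRecord:
    """One simulated single-nucleotide substitution."""

    branch: str
    time: float  # position along the branch, in branch-length units
    site: int  # 0-based codon site
    codon_pos: int  # 0..2
    from_nt: str
    to_nt: str
    from_codon: str
    to_codon: str
    synonymous: bool
    cpg_context: bool


@dataclass
class ScenarioTruth:
    """Ground truth attached to a simulated alignment."""

    seed: int
    true_omega: dict[int, float]
    events: list[SubstitutionRecord]
    node_states: dict[str, str]  # node label -> full nucleotide sequence
    tree: Tree  # tree with all nodes labelled (matches node_states keys)
    scenario_events: list[tuple[str, str, float]] = field(default_factory=list)

    def branch_counts(self) -> dict[str, dict[str, int]]:
        """Per-branch substitution counts: total / synonymous / nonsynonymous /
        CpG-context."""
        out: dict[str, dict[str, int]] = {}
        for ev in self.events:
            rec = out.setdefault(
                ev.branch, {"total": 0, "synonymous": 0, "nonsynonymous": 0, "cpg": 0}
            )
            rec["total"] += 1
            rec["synonymous" if ev.synonymous else "nonsynonymous"] += 1
            if ev.cpg_context:
                rec["cpg"] += 1
        return out


class _GillespieEngine:
    """Per-branch exact simulation of the codon process with CpG overlay."""

    def __init__(self, params: CodonModelParams, code: GeneticCode, cfg: SimConfig):
        self.code = code
        self.params = params
        self.cfg = cfg
        st = _structure(code)
        n = st.n
        # neighbour tables: for each codon index, arrays of target index,
        # changed position, from/to nucleotide, base rate factor pi_j*kappa^ts
        self.neigh: list[dict] = []
        base = params.pi[st.j].copy()
        base[st.transition] *= params.kappa
        self.scales = {
            part: build_rate_matrix(params, part, code).scale
            for part in params.omega_by_partition
        }
        by_i: dict[int, list[int]] = {}
        for idx in range(len(st.i)):
            by_i.setdefault(int(st.i[idx]), []).append(idx)
        sense = code.sense_codons
        for i in range(n):
            idxs = by_i.get(i, [])
            self.neigh.append(
                {
                    "j": st.j[idxs],
                    "pos": np.array([next(p for p in range(3) if sense[i][p] != sense[st.j[k]][p]) for k in idxs], dtype=int)
                    if idxs
                    else np.empty(0, dtype=int),
                    "base": base[idxs],
                    "nonsyn": st.nonsyn[idxs],
                }
            )

    def _site_rates(self, seq: list[int], site: int, omega: float, scale: float) -> np.ndarray:
        """Rates to each single-nucleotide neighbour of the codon at ``site``."""
        info = self.neigh[seq[site]]
        rates = info["base"].copy()
        rates[info["nonsyn"]] *= omega
        if self.cfg.cpg_bias > 1.0:
            sense = self.code.sense_codons
            current = sense[seq[site]]
            for k in range(len(rates)):
                p = info["pos"][k]
                to_nt = sense[info["j"][k]][p]
                from_nt = current[p]
                if self._is_cpg_change(seq, site, p, from_nt, to_nt):
                    rates[k] *= self.cfg.cpg_bias
        return rates / scale

    def _nt_at(self, seq: list[int], site: int, p: int) -> str:
        """Nucleotide at absolute ORF position 3*site+p, with fixed flanks."""
        pos = 3 * site + p
        if pos < 0:
            return self.cfg.flank5
        if pos >= 3 * len(seq):
            return self.cfg.flank3
        return self.code.sense_codons[seq[pos // 3]][pos % 3]

    def _is_cpg_change(
        self, seq: list[int], site: int, p: int, from_nt: str, to_nt: str
    ) -> bool:
        abs_pos = 3 * site + p
        if from_nt == "C" and to_nt == "T":
            nxt = self._nt_at(seq, (abs_pos + 1) // 3, (abs_pos + 1) % 3)
            return nxt == "G"
        if from_nt == "G" and to_nt == "A":
            prv = self._nt_at(seq, (abs_pos - 1) // 3, (abs_pos - 1) % 3)
            return prv == "C"
        return False

    def evolve_branch(
        self,
        seq: list[int],
        branch_length: float,
        partition: int,
        branch_label: str,
        rng: np.random.Generator,
        events: list[SubstitutionRecord],
    ) -> list[int]:
        """Evolve a copy of ``seq`` along one branch, appending events."""
        seq = list(seq)
        if branch_length <= 0:
            return seq
        omega = self.params.omega_by_partition[partition]
        scale = self.scales[partition]
        n_sites = len(seq)
        site_rates = [self._site_rates(seq, s, omega, scale) for s in range(n_sites)]
        totals = np.array([r.sum() for r in site_rates])
        t = 0.0
        sense = self.code.sense_codons
        while True:
            total = totals.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= branch_length:
                break
            site = int(rng.choice(n_sites, p=totals / total))
            rates = site_rates[site]
            k = int(rng.choice(len(rates), p=rates / rates.sum()))
            info = self.neigh[seq[site]]
            j = int(info["j"][k])
            p = int(info["pos"][k])
            from_codon, to_codon = sense[seq[site]], sense[j]
            from_nt, to_nt = from_codon[p], to_codon[p]
            cpg = self._is_cpg_change(seq, site, p, from_nt, to_nt)
            events.append(
                SubstitutionRecord(
                    branch=branch_label,
                    time=t,
                    site=site,
                    codon_pos=p,
                    from_nt=from_nt,
                    to_nt=to_nt,
                    from_codon=from_codon,
                    to_codon=to_codon,
                    synonymous=bool(not info["nonsyn"][k]),
                    cpg_context=cpg,
                )
            )
            seq[site] = j
            # context of the neighbouring sites may have changed
            for s in (site - 1, site, site + 1):
                if 0 <= s < n_sites:
                    site_rates[s] = self._site_rates(seq, s, omega, scale)
                    totals[s] = site_rates[s].sum()
        return seq


def _label_nodes(tree: Tree) -> Tree:
    """Copy the tree, giving every unnamed internal node a stable label."""
    tree = tree.copy()
    counter = 0
    for node in tree.postorder():
        if node.name is None:
            node.name = f"node{counter}"
            counter += 1
    return tree


def simulate_alignment(cfg: SimConfig) -> tuple[CodonAlignment, ScenarioTruth]:
    """Simulate codon sequences along ``cfg.tree`` under the clades model.

    The root sequence is drawn from the stationary distribution; each branch
    is evolved with the Gillespie engine under that branch's partition
    omega.  Returns the leaf alignment and the full event-level truth
    (including internal-node sequences).
    """
    rng = np.random.default_rng(cfg.seed)
    code = STANDARD_CODE
    tree = _label_nodes(cfg.tree)
    engine = _GillespieEngine(cfg.params, code, cfg)
    events: list[SubstitutionRecord] = []
    node_states: dict[str, str] = {}
    seqs: dict[int, list[int]] = {}

    root_seq = list(rng.choice(len(code.sense_codons), size=cfg.n_codons, p=cfg.params.pi))
    seqs[id(tree.root)] = root_seq
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            parent_seq = seqs[id(node.parent)]
            seqs[id(node)] = engine.evolve_branch(
                parent_seq,
                node.length or 0.0,
                node.partition,
                node.name,
                rng,
                events,
            )
        node_states[node.name] = "".join(
            code.sense_codons[c] for c in seqs[id(node)]
        )
    leaf_names = tree.leaf_names()
    aln = CodonAlignment(leaf_names, [node_states[n] for n in leaf_names])
    truth = ScenarioTruth(
        seed=cfg.seed,
        true_omega=dict(cfg.params.omega_by_partition),
        events=events,
        node_states=node_states,
        tree=tree,
    )
    return aln, truth


def graft_retrogene_clade(
    base_tree: Tree,
    retro_branch_point: str,
    *,
    attach_fraction: float = 0.5,
    dup_delay: float = 0.02,
    tip_length: float = 0.05,
    names: tuple[str, str] = ("retro1", "retro2"),
) -> Tree:
    """Graft a retrogene clade onto a species tree.

    The branch above ``retro_branch_point`` is split ``attach_fraction`` of
    the way down from its parent; at the split a retro stem of length
    ``dup_delay`` leads to a duplication node whose two children (the two
    retrocopies) have ``tip_length`` branches.  The stem and both tips are
    labelled partition 1 (the foreground clade).
    """
    tree = base_tree.copy()
    host = tree.find(retro_branch_point)
    if host.parent is None:
        raise ValueError("cannot graft onto the root branch")
    if host.length is None:
        raise ValueError("graft branch has no length")
    parent = host.parent
    graft = Node(None, host.length * attach_fraction, host.partition)
    idx = parent.children.index(host)
    parent.children[idx] = graft
    graft.parent = parent
    graft.add_child(host)
    host.length = host.length * (1.0 - attach_fraction)
    dup = Node(None, dup_delay, 1)
    dup._label_explicit = True
    graft.add_child(dup)
    for name in names:
        tip = Node(name, tip_length, 1)
        tip._label_explicit = True
        dup.add_child(tip)
    return Tree(tree.root)


def simulate_retrogene_scenario(
    base_tree: Tree,
    retro_branch_point: str,
    dup_delay: float,
    cfg_params: CodonModelParams,
    n_codons: int,
    seed: int,
    *,
    attach_fraction: float = 0.5,
    tip_length: float = 0.05,
    cpg_bias: float = 1.0,
    names: tuple[str, str] = ("retro1", "retro2"),
) -> tuple[Tree, CodonAlignment, ScenarioTruth]:
    """Simulate the retrotransposition + duplication scenario end to end.

    A retro clade (stem + duplication split) is grafted onto the species
    tree at ``retro_branch_point``, labelled as foreground (partition 1),
    and sequences are simulated under the background/foreground omegas of
    ``cfg_params``.  The grafted tree, the leaf alignment and the truth
    record (with the retrotransposition and duplication events) are
    returned.
    """
    if dup_delay < 0:
        raise ValueError("dup_delay must be >= 0")
    grafted = graft_retrogene_clade(
        base_tree,
        retro_branch_point,
        attach_fraction=attach_fraction,
        dup_delay=dup_delay,
        tip_length=tip_length,
        names=names,
    )
    cfg = SimConfig(
        tree=grafted, params=cfg_params, n_codons=n_codons, seed=seed, cpg_bias=cpg_bias
    )
    aln, truth = simulate_alignment(cfg)
    truth.scenario_events = [
        ("retrotransposition", retro_branch_point, attach_fraction),
        ("duplication", names[0] + "+" + names[1], dup_delay),
    ]
    return grafted, aln, truth


# ---------------------------------------------------------------- loci
@dataclass
class SyntheticLocus:
    """A genomic segment with a planted retrocopy insertion.

    The locus is ``left + TTTT + TSD + insert + TSD + right``: the L1
    endonuclease motif 5'-TTTT/A-3' sits immediately 5' of the first
    target-site-duplication copy (which starts with the A of the motif),
    and the insert lies between the two exact TSD copies.
    """

    sequence: str
    insert_interval: tuple[int, int]  # 0-based half-open
    tsd: str
    tsd5_interval: tuple[int, int]
    tsd3_interval: tuple[int, int]
    en_site: int  # cleavage point (0-based offset of the base after TTTT)
    strand: str = "+"
    seed: int | None = None


def simulate_insertion_locus(
    flank_len: int,
    tsd_len: int,
    insert_seq: str,
    seed: int,
) -> SyntheticLocus:
    """Generate a random locus with a planted retrocopy, TSDs and EN site.

    ``tsd_len >= 1`` plants two exact direct repeats (the first base is the
    A of the TTTT/A cleavage motif); ``tsd_len = 0`` plants the insert with
    no duplication.  Flanking sequence is uniform random, with the single
    base adjacent to each TSD copy adjusted so the planted repeat cannot be
    extended by chance (keeping the planted coordinates recoverable
    exactly).
    """
    if not insert_seq:
        raise ValueError("insert_seq must be non-empty")
    if tsd_len < 0:
        raise ValueError("tsd_len must be >= 0")
    if flank_len < tsd_len + 8:
        raise ValueError("flank too short for the EN motif plus the TSD")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, size=flank_len - 4))
    right = "".join(rng.choice(bases, size=flank_len))
    insert_seq = insert_seq.upper()
    if tsd_len > 0:
        tsd = "A" + "".join(rng.choice(bases, size=tsd_len - 1))
        # The base immediately 5' of the 5' TSD copy is always the last T of
        # the endonuclease motif, so the planted repeat would extend by chance
        # whenever the base after the 3' copy is also T; force it to differ.
        if right[0] == "T":
            right = "C" + right[1:]
    else:
        tsd = ""
    seq = left + "TTTT" + tsd + insert_seq + tsd + right
    en_site = len(left) + 4
    ins_start = en_site + tsd_len
    ins_end = ins_start + len(insert_seq)
    return SyntheticLocus(
        sequence=seq,
        insert_interval=(ins_start, ins_end),
        tsd=tsd,
        tsd5_interval=(en_site, en_site + tsd_len),
        tsd3_interval=(ins_end, ins_end + tsd_len),
        en_site=en_site,
        seed=seed,
    )
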