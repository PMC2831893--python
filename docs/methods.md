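# Methods

## Codon substitution model

The substitution process runs on the 61 sense codons of the standard
nuclear genetic code (the code table is injectable for other systems;
stop codons are never valid states).  The instantaneous rate between
codons differing at exactly one nucleotide position is

q(i→j) ∝ π_j · κ^t(i,j) · ω_p^n(i,j),

where t(i,j) indicates a transition, n(i,j) a nonsynonymous change, and p
is the partition of the branch being traversed.  Pairs differing at two or
more positions have rate zero.  The diagonal makes rows sum to zero and
each partition's matrix is divided by −Σᵢ πᵢ qᵢᵢ, so a branch length of 1
means one expected codon substitution at stationarity under that branch's
ω.  The chain is time-reversible (detailed balance πᵢ qᵢⱼ = πⱼ qⱼᵢ holds by
construction), which makes the likelihood invariant to root placement and
lets us compute P(t) = exp(Qt) by a single symmetric eigendecomposition of
diag(√π) Q diag(√π)⁻¹, reused for every branch length.

**Stationary frequencies.**  Default F3x4: nucleotide frequencies are
counted separately at the three codon positions over all taxa and retained
columns; each sense codon's probability is the product of its three
positional frequencies, renormalized over the 61.  A base missing entirely
from one position zeroes every codon using it — this is permitted but
reported as a warning, because downstream likelihoods then assign those
codons probability zero.  F61 (empirical codon counts, with a 0.5
pseudocount) is available as an option.

**Partitions.**  Branch labels on the tree define the ω structure:
partition 0 is the background (ω₁), partition 1 the foreground clade (ω₂).
In the retrogene scenario the foreground is the whole retro clade —
stem branch, duplication node and both retrocopy tips.  The Newick label
`#1` therefore propagates to the subtree below it by default; stem-only
labelling is available by flag.

## Input handling

Alignments must be pre-aligned, in-frame FASTA.  Columns containing a gap,
an ambiguity code or (optionally) a stop codon in *any* taxon are dropped
before analysis (complete-case filtering).  No gap or ambiguity model is
attempted: the likelihood machinery only ever sees the 61 sense states,
and the retained-column mask is kept so filtered coordinates can be mapped
back.  Stop codons are an error by default since intact-ORF alignments
should not contain them.

## Likelihood, optimization, uncertainty

Site patterns are compressed with multiplicities before any evaluation;
partials are rescaled per internal node to prevent underflow.  The fit
maximizes lnL jointly over κ, the per-partition ω and all branch lengths,
on log-transformed parameters with L-BFGS-B.  Branch-length gradients are
analytic (one preorder sweep computing, for every branch, the inner
product of the complement partial with Q·P(t)·partial); κ/ω derivatives
use central finite differences on the log scale.  Bounds:
ω ∈ [10⁻⁴, 50] (the lower bound keeps a fully conserved clade
representable as a boundary estimate), κ ∈ [0.05, 50], branch lengths
∈ [10⁻⁸, 20].  Defaults: start at κ = 2, ω = 0.4, branch lengths from the
input tree (or a pairwise p-distance heuristic when absent), three
multistarts jittered ±70% in log space from a seeded generator.  The
multistarts have never changed the optimum on the simulated study
conditions, so batch experiments in the test-suite and acceptance script
use a single start.

Standard errors are Wald: the observed information is the negated central
finite-difference Hessian of lnL in (κ, ω…) at the MLE with branch lengths
held at their estimates.  Holding branch lengths fixed slightly understates
the uncertainty relative to profiling them out; on the study conditions the
difference is well inside the Wald approximation error (3-SE recovery
checks pass).  An SE is reported as *undefined* when the estimate sits at a
bound (within 1% relative) or the information matrix is not positive
definite — the typical case being a fully conserved foreground clade whose
ω̂₂ collapses to the lower bound.

The LRT statistic Δ = 2(lnL_clades − lnL_M0) is clamped at zero (optimizer
noise can make it very slightly negative) and referred to χ² with df equal
to the extra ω count (1 for clades vs M0).  Type-I calibration under the
null is checked empirically — the rejection rate at the χ²₁ 95% point on
data simulated under M0 falls in [0.025, 0.08]; mild conservatism is
expected because the null sometimes puts Δ on the boundary.

## Synthetic-data generator

Sequences are simulated **event by event** (Gillespie) along each branch
rather than by sampling leaf states from P(t), so that every substitution
exists as a recorded event with branch, codon site, nucleotide change,
synonymous/nonsynonymous class and CpG context, and all internal-node
sequences are stored.  This event-level truth is what the parsimony and
CpG-annotation stages are validated against.  Time within a branch is
measured in the same expected-substitutions-per-codon units as the
likelihood side (rates divided by the partition's matrix scale).

The CpG overlay multiplies the rate of C→T changes followed by G, and of
G→A changes preceded by C, by `cpg_bias` (≥ 1); context is re-evaluated
after every event and crosses codon boundaries; the bases flanking the ORF
are fixed in the configuration (defaults T…A).  With `cpg_bias = 1` the
overlay is exactly a no-op.  The overlay perturbs the stationary
distribution away from π — it is a mutation-bias emulator for testing the
annotation stage, not part of the inferential model.

The retrogene scenario grafts a foreground clade onto a species tree: the
branch above the host lineage is split, a stem of length `dup_delay` leads
to the duplication node, and the two retrocopy tips hang below it.  The
default study tree covers seven mammalian ortholog lineages with the clade
grafted onto the mouse terminal branch and a deliberately short stem
(duplication shortly after retrotransposition).  Branch lengths of this
fixture (0.02–0.25 expected substitutions per codon) are package choices
on the scale typical of mammalian ortholog ORF divergence; the study
conditions used throughout testing are ω₁ = 0.05, ω₂ = 0.30, κ = 2,
250 codons.

Synthetic insertion loci are built as
`flank + TTTT + TSD + insert + TSD + flank`: the endonuclease motif
5'-TTTT/A-3' sits immediately 5' of the first target-site-duplication
copy, whose first base is the A of the motif.  One flank base adjacent to
the repeat is adjusted deterministically so the planted repeat cannot be
extended by chance, keeping planted coordinates exactly recoverable.
What the generator does *not* emulate: 5' truncation and poly-A tails of
real L1 inserts, indels, sequencing error, rate variation across sites,
and selection on the flanks — so passing tests demonstrate correctness of
the algorithms under the model, not robustness to every feature of real
genomic data.

## Ancestral reconstruction and CpG annotation

Each nucleotide position of a tracked codon is reconstructed independently
with the Hartigan formulation of minimum-change parsimony (exact on binary
and multifurcating rooted trees); the codon at a node is the triple of
position states.  The top-down pass resolves ambiguity by preferring the
parent's state when optimal (ties broken to the lexicographically smallest
state, which makes results deterministic); the full optimal-state sets are
retained alongside the single refined assignment.  Events are placed on
branches where parent and child assignments differ; the total event count
equals the minimum change count, and parsimony is, as always, a lower
bound on the true number of changes (verified against simulation truth).
Rooting is taken from the input tree, or from an explicit outgroup
(rerooting on its branch).

An event is flagged CpG-consistent when it is C→T with the next base G, or
G→A with the previous base C, in the *parent* context — taken from
supplied node sequences (e.g. simulation truth) or assembled from the
reconstruction when all sites are tracked.  Missing context at a sequence
edge, or an ambiguous neighbouring base, yields an *unknown* flag rather
than false.

## Locus diagnostics

*In-silico PCR* requires a unique exact forward-primer match and a unique
reverse-complement match downstream; amplicon coordinates are
primer-inclusive, which is the convention that reproduces gel-measured
product sizes (a 1186 bp product digesting to 213 + 973 bp only adds up
with primer-inclusive lengths).  Mismatch tolerance is opt-in and never
allowed in the 3'-terminal 3 nt.  Templates are linear.

*Digests* use IUPAC patterns with a cut offset (NlaIV = GGNNCC cut bluntly
after position 3); overlapping sites are all counted, and fragments between
successive cuts always sum to the input length.  Enzymes live in a small
editable table.

*TSD detection* looks for the longest direct repeat whose 5' copy ends at
the insert's 5' boundary and whose 3' copy starts at its 3' boundary,
within a mismatch budget; repeats shorter than 6 bp (default) are not
called.  When the base run immediately 5' of the repeat is TTTT, the
cleavage coordinate is attached to the call.

*Endonuclease scans* use the strict TTTT/A target by default, reporting
the extended TTTT/AA form as a flag on each hit, and scan both strands
with minus-strand hits mapped to plus-strand coordinates.

*Protein diffs* compare equal-length ORFs positionwise (retrocopies are
unspliced full-length copies, so no alignment is attempted; a length
mismatch is an error, not an implicit alignment).  Substitutions are
annotated with every conserved GTPase motif covering the residue: G1/Walker
A (10–17), G2 (28–40), G3 (57–60), G4 (116–119), and the effector domain
(20–45) split into the general recognition motif (32–40) and the
specificity regions (20–31, 41–45); residue numbering is 1-based
throughout.  Note for users of the Rap1 retrocopy examples: published
materials differ in places on which mouse retrocopy carries the T35M
substitution; this package's examples and documentation follow the
residue-map assignment (T35M on the triple-substitution copy, retro2, with
A59V on retro1) and surface the conflict rather than silently "fixing"
either source.

## Verification scale

The acceptance script and tests verify, at these problem sizes: pruning
vs exhaustive enumeration on 30 random quartets of 5 codons (agreement to
1e-8); ω recovery on 20 simulated 9-taxon, 250-codon clades datasets
(mean ω̂₂ within 0.05, each estimate within 3 SEs); LRT type-I error on
300 simulated 5-taxon, 200-codon null datasets; basal-topology invariance
of ω̂ to 1e-3 on one 300-codon dataset; parsimony vs brute force on 50
random 5-leaf cases; and TSD/EN recovery on 100 planted loci.  These sizes
were chosen as the smallest at which each property is sharply testable.

## Known limitations

Site-homogeneous ω only (no site-mixture or positive-selection site
models), no gamma rate variation, no gap model, standard genetic code by
default, linear templates only, and maximum-parsimony (not ML) ancestral
states.  Real-sequence reproduction of the published ω₂ values depends on
assembling the same ortholog alignments from GenBank, which the package
does not download; those checks run only when the user supplies the
sequences.
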