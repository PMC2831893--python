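"""Felsenstein pruning likelihood for the partitioned codon model.

Site patterns are compressed with multiplicities before any likelihood
evaluation.  Partial likelihoods are rescaled per internal node to guard
against underflow on deep trees; all reported quantities are on the
log scale.  Branch-length derivatives are computed analytically from a
single downward (preorder) pass, which makes joint optimization of branch
lengths tractable.
"""

from __future__ import annotations

import numpy as np

from .codonmodel import CodonModelParams, RateMatrix, build_rate_matrix
from .genetics import GeneticCode, STANDARD_CODE
from .seqio import CodonAlignment
from .trees import Node, Tree

_TINY = 1e-300


class PruningLikelihood:
    """Likelihood engine binding one alignment to one tree.

    Construction performs taxon matching and site-pattern compression;
    :meth:`loglik` and :meth:`loglik_and_branch_grad` then evaluate the
    model for arbitrary parameter values and branch lengths.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: Tree,
        code: GeneticCode = STANDARD_CODE,
    ) -> None:
        leaf_names = tree.leaf_names()
        if sorted(leaf_names) != sorted(aln.taxa):
            raise ValueError(
                f"tree leaves {sorted(leaf_names)} do not match "
                f"alignment taxa {sorted(aln.taxa)}"
            )
        self.code = code
        self.tree = tree
        states = aln.codon_indices(code)  # (n_taxa, n_sites)
        order = [aln.taxa.index(name) for name in leaf_names]
        states = states[order, :]
        patterns, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_leaves, n_patterns), leaf order = tree order
        self.pattern_index = inverse
        self.counts = counts.astype(float)
        self.n_sites = states.shape[1]
        self.n_patterns = patterns.shape[0]

        # Flatten the tree once: postorder node list with integer ids.
        self.nodes: list[Node] = list(tree.postorder())
        self._node_id = {id(n): i for i, n in enumerate(self.nodes)}
        self.branch_nodes: list[Node] = [n for n in self.nodes if n is not tree.root]
        self._leaf_row = {}
        for row, name in enumerate(leaf_names):
            self._leaf_row[name] = row

    # ------------------------------------------------------------------ helpers
    def branch_lengths(self) -> np.ndarray:
        """Current branch lengths in engine order (postorder, root excluded)."""
        return np.array(
            [n.length if n.length is not None else 0.0 for n in self.branch_nodes]
        )

    def branch_partitions(self) -> np.ndarray:
        return np.array([n.partition for n in self.branch_nodes])

    def _matrices(self, params: CodonModelParams) -> dict[int, RateMatrix]:
        return {
            part: build_rate_matrix(params, part, self.code)
            for part in params.omega_by_partition
        }

    # ------------------------------------------------------------------ pruning
    def _forward(self, params: CodonModelParams, lengths: np.ndarray):
        """Postorder pass: per-branch messages, per-node partials and scales."""
        mats = self._matrices(params)
        t_by_node = {id(n): float(t) for n, t in zip(self.branch_nodes, lengths)}
        messages: dict[int, np.ndarray] = {}
        partials: dict[int, np.ndarray] = {}
        Ps: dict[int, np.ndarray] = {}
        log_scale = np.zeros(self.n_patterns)
        scale_at: dict[int, np.ndarray] = {}
        for node in self.nodes:
            if node.is_leaf and node.parent is not None:
                continue
            prod = None
            for child in node.children:
                P = mats[child.partition].transition_probabilities(
                    t_by_node[id(child)]
                )
                Ps[id(child)] = P
                if child.is_leaf:
                    msg = P[:, self.patterns[self._leaf_row[child.name]]]
                else:
                    msg = P @ partials[id(child)]
                messages[id(child)] = msg
                prod = msg.copy() if prod is None else prod * msg
            if prod is None:  # single-leaf tree: root is the leaf
                prod = np.zeros((len(params.pi), self.n_patterns))
                prod[self.patterns[self._leaf_row[node.name]], np.arange(self.n_patterns)] = 1.0
            s = prod.max(axis=0)
            s = np.where(s > 0, s, 1.0)
            prod /= s
            scale_at[id(node)] = s
            log_scale += np.log(s)
            partials[id(node)] = prod
        root_partial = partials[id(self.tree.root)]
        site_lik = params.pi @ root_partial  # scaled site likelihoods
        return mats, t_by_node, messages, partials, Ps, scale_at, site_lik, log_scale

    def loglik(self, params: CodonModelParams, lengths: np.ndarray | None = None) -> float:
        """Log-likelihood of the alignment given tree, lengths and parameters."""
        if lengths is None:
            lengths = self.branch_lengths()
        *_, site_lik, log_scale = self._forward(params, np.asarray(lengths, float))
        return float(self.counts @ (np.log(np.maximum(site_lik, _TINY)) + log_scale))

    def loglik_and_branch_grad(
        self, params: CodonModelParams, lengths: np.ndarray | None = None
    ) -> tuple[float, np.ndarray]:
        """Log-likelihood and its gradient with respect to every branch length.

        The gradient uses the identity d lnL / d t_b =
        sum_sites w * F_b . (Q P(t_b) C_b) / L_site, with F_b the partial
        likelihood of the tree complement at the parent end of branch b,
        obtained by one preorder sweep.
        """
        if lengths is None:
            lengths = self.branch_lengths()
        lengths = np.asarray(lengths, float)
        (
            mats,
            t_by_node,
            messages,
            partials,
            Ps,
            scale_at,
            site_lik,
            log_scale,
        ) = self._forward(params, lengths)
        lnl = float(self.counts @ (np.log(np.maximum(site_lik, _TINY)) + log_scale))
        inv_sl = self.counts / np.maximum(site_lik, _TINY)

        above: dict[int, np.ndarray] = {
            id(self.tree.root): np.repeat(params.pi[:, None], self.n_patterns, axis=1)
        }
        grad = np.zeros(len(self.branch_nodes))
        branch_pos = {id(n): k for k, n in enumerate(self.branch_nodes)}
        for node in self.tree.preorder():
            if node.is_leaf and node.parent is not None:
                continue
            A = above[id(node)] / scale_at[id(node)]
            msgs = [messages[id(c)] for c in node.children]
            k = len(msgs)
            # prefix/suffix products over sibling messages
            prefix = [None] * (k + 1)
            suffix = [None] * (k + 1)
            prefix[0] = np.ones_like(A)
            for i in range(k):
                prefix[i + 1] = prefix[i] * msgs[i]
            suffix[k] = np.ones_like(A)
            for i in range(k - 1, -1, -1):
                suffix[i] = suffix[i + 1] * msgs[i]
            for i, child in enumerate(node.children):
                F = A * prefix[i] * suffix[i + 1]
                rm = mats[child.partition]
                t = t_by_node[id(child)]
                dP = rm.dP_dt(t)
                if child.is_leaf:
                    dmsg = dP[:, self.patterns[self._leaf_row[child.name]]]
                else:
                    dmsg = dP @ partials[id(child)]
                grad[branch_pos[id(child)]] = float(
                    inv_sl @ (F * dmsg).sum(axis=0)
                )
                if not child.is_leaf:
                    above[id(child)] = Ps[id(child)].T @ F
        return lnl, grad


def log_likelihood(
    aln: CodonAlignment,
    tree: Tree,
    params: CodonModelParams,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """One-shot pruning log-likelihood (builds the engine and evaluates)."""
    return PruningLikelihood(aln, tree, code).loglik(params)
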