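"""Time-continuous Markov codon substitution model.

The model follows the classical codon-level formulation for dN/dS
estimation: instantaneous substitution between sense codons ``i`` and ``j``
is allowed only when they differ at exactly one nucleotide position, with
rate proportional to the target codon's stationary frequency, multiplied by
the transition/transversion ratio ``kappa`` when the nucleotide change is a
transition and by the nonsynonymous/synonymous rate ratio ``omega`` when
the amino acid changes.  Each partition of the tree (background vs a
foreground clade such as a retrogene clade) carries its own omega and
therefore its own rate matrix.

Matrices are scaled so that one unit of branch length equals one expected
codon substitution at stationarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genetics import GeneticCode, STANDARD_CODE, is_transition
from .seqio import CodonAlignment

N_SENSE = 61


@dataclass
class CodonModelParams:
    """Parameters of the partitioned codon model.

    Attributes
    ----------
    kappa
        Transition/transversion rate ratio (> 0).
    omega_by_partition
        Map from tree partition label to its dN/dS ratio (>= 0).  Partition
        0 is the background; a foreground clade uses label 1.
    pi
        Stationary frequencies over the 61 sense codons (sum to 1).
    """

    kappa: float
    omega_by_partition: dict[int, float]
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        for part, omega in self.omega_by_partition.items():
            if omega < 0:
                raise ValueError(f"omega for partition {part} is negative: {omega}")
        if self.pi.shape != (N_SENSE,):
            raise ValueError(f"pi must have {N_SENSE} entries, got {self.pi.shape}")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi entries must be non-negative and sum to 1")

    @property
    def n_partitions(self) -> int:
        return len(self.omega_by_partition)


class _CodeStructure:
    """Single-nucleotide-neighbour structure of a genetic code, cached."""

    def __init__(self, code: GeneticCode) -> None:
        n = len(code.sense_codons)
        pairs_i, pairs_j = [], []
        transition, nonsyn = [], []
        for i, ci in enumerate(code.sense_codons):
            for j, cj in enumerate(code.sense_codons):
                if i == j:
                    continue
                diff = [p for p in range(3) if ci[p] != cj[p]]
                if len(diff) != 1:
                    continue
                (p,) = diff
                pairs_i.append(i)
                pairs_j.append(j)
                transition.append(is_transition(ci[p], cj[p]))
                nonsyn.append(not code.is_synonymous(ci, cj))
        self.n = n
        self.i = np.array(pairs_i)
        self.j = np.array(pairs_j)
        self.transition = np.array(transition, dtype=bool)
        self.nonsyn = np.array(nonsyn, dtype=bool)


_STRUCTURE_CACHE: dict[int, _CodeStructure] = {}


def _structure(code: GeneticCode) -> _CodeStructure:
    key = id(code)
    if key not in _STRUCTURE_CACHE:
        _STRUCTURE_CACHE[key] = _CodeStructure(code)
    return _STRUCTURE_CACHE[key]


def f3x4_frequencies(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Stationary sense-codon frequencies from positional base composition.

    Counts nucleotide frequencies separately at the three codon positions
    over all taxa and retained columns, forms the product
    ``pi(c) = f1(c1) f2(c2) f3(c3)`` for each sense codon, and renormalizes
    over the 61 sense codons.  A base absent from some codon position zeroes
    every sense codon using it; this is permitted but reported as a warning.
    """
    if aln.unit != 3:
        raise ValueError("F3x4 frequencies require a codon-mode alignment")
    counts = np.zeros((3, 4))
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in aln.rows:
        for j in range(aln.n_sites):
            for p in range(3):
                base = row[3 * j + p]
                if base in base_index:
                    counts[p, base_index[base]] += 1
    if counts.sum() == 0:
        raise ValueError("empty alignment: no bases to count")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, base_index[c[0]]]
            * freqs[1, base_index[c[1]]]
            * freqs[2, base_index[c[2]]]
            for c in code.sense_codons
        ]
    )
    zeroed = [c for c, p in zip(code.sense_codons, pi) if p == 0.0]
    if zeroed:
        warnings.warn(
            f"{len(zeroed)} sense codons have zero F3x4 frequency "
            f"(absent positional bases): {zeroed[:5]}...",
            RuntimeWarning,
            stacklevel=2,
        )
    total = pi.sum()
    if total == 0:
        raise ValueError("all sense-codon frequencies are zero")
    return pi / total


def f61_frequencies(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE, *, pseudocount: float = 0.0
) -> np.ndarray:
    """Empirical sense-codon frequencies (the F61 alternative to F3x4)."""
    counts = np.full(N_SENSE, pseudocount, dtype=float)
    for row in aln.rows:
        for j in range(aln.n_sites):
            k = code.codon_index.get(row[3 * j : 3 * j + 3])
            if k is not None:
                counts[k] += 1
    if counts.sum() == 0:
        raise ValueError("no sense codons observed")
    return counts / counts.sum()


@dataclass
class RateMatrix:
    """A scaled instantaneous rate matrix with its cached eigendecomposition.

    ``Q`` is 61x61 with rows summing to zero; branch lengths applied to it
    are expected substitutions per codon.  The eigendecomposition of the
    pi^(1/2)-symmetrized matrix (real spectrum by reversibility) is computed
    once and reused for every transition-probability evaluation.
    """

    Q: np.ndarray
    pi: np.ndarray
    scale: float  # divisor applied to the unscaled matrix
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    def _decompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            with np.errstate(divide="ignore", invalid="ignore"):
                inv_sqrt = np.where(sqrt_pi > 0, 1.0 / sqrt_pi, 0.0)
            sym = (sqrt_pi[:, None] * self.Q) * inv_sqrt[None, :]
            sym = 0.5 * (sym + sym.T)  # enforce symmetry against rounding
            eigval, eigvec = np.linalg.eigh(sym)
            left = inv_sqrt[:, None] * eigvec  # columns: right eigenvectors of Q
            right = eigvec.T * sqrt_pi[None, :]  # rows: left eigenvectors
            self._eig = (eigval, left, right)
        return self._eig

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), row-stochastic."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        eigval, left, right = self._decompose()
        P = (left * np.exp(eigval * t)[None, :]) @ right
        np.clip(P, 0.0, None, out=P)
        return P

    def dP_dt(self, t: float) -> np.ndarray:
        """Derivative of P(t) with respect to branch length: Q exp(Qt)."""
        eigval, left, right = self._decompose()
        return (left * (eigval * np.exp(eigval * t))[None, :]) @ right


def build_rate_matrix(
    params: CodonModelParams,
    partition: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> RateMatrix:
    """Build the scaled rate matrix for one tree partition.

    Off-diagonal rates are ``pi_j`` times ``kappa`` for transitions and
    ``omega`` for nonsynonymous changes; codon pairs differing at more than
    one position get rate zero.  The matrix is rescaled so the expected
    substitution rate at stationarity is 1 per codon.
    """
    if partition not in params.omega_by_partition:
        raise ValueError(
            f"partition {partition} not in omega map "
            f"{sorted(params.omega_by_partition)}"
        )
    omega = params.omega_by_partition[partition]
    st = _structure(code)
    Q = np.zeros((st.n, st.n))
    rates = params.pi[st.j].copy()
    rates[st.transition] *= params.kappa
    rates[st.nonsyn] *= omega
    Q[st.i, st.j] = rates
    Q[np.diag_indices(st.n)] = -Q.sum(axis=1)
    scale = float(-(params.pi * np.diag(Q)).sum())
    if scale <= 0:
        raise ValueError("degenerate rate matrix: zero total rate")
    Q /= scale
    return RateMatrix(Q=Q, pi=params.pi.copy(), scale=scale)


def transition_probabilities(Q: RateMatrix, t: float) -> np.ndarray:
    """Functional wrapper around :meth:`RateMatrix.transition_probabilities`."""
    return Q.transition_probabilities(t)
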