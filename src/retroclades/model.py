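"""ML fitting of one-ratio (M0) and clade-partitioned codon models.

The public surface follows the model/results idiom: a
:class:`CladeDnDsModel` binds data (codon alignment + labelled tree) and
model structure; :meth:`CladeDnDsModel.fit` maximizes the likelihood over
kappa, the per-partition omegas and all branch lengths, returning a
:class:`CodonFitResult` that carries estimates, standard errors and a
``summary()`` table.  The nested likelihood-ratio test between the
one-ratio and clades models is exposed both as
:meth:`CodonFitResult.compare_lr_test` and the functional
:func:`likelihood_ratio_test`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .codonmodel import CodonModelParams, f3x4_frequencies, f61_frequencies
from .genetics import GeneticCode, STANDARD_CODE
from .likelihood import PruningLikelihood
from .seqio import CodonAlignment, filter_codon_columns
from .trees import Tree

# Bounds chosen to be numerically safe while covering the biological range;
# the omega lower bound keeps a fully conserved clade representable as a
# boundary estimate (reported as 1e-4, with SE undefined).
OMEGA_BOUNDS = (1e-4, 50.0)
KAPPA_BOUNDS = (0.05, 50.0)
BRANCH_BOUNDS = (1e-8, 20.0)
_BOUNDARY_RTOL = 1e-2


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models.

    ``delta`` is twice the log-likelihood difference (clamped at zero to
    absorb optimizer noise), compared against a chi-square distribution
    with ``df`` degrees of freedom.
    """

    delta: float
    df: int
    p: float

    def __str__(self) -> str:
        return f"LRT: delta = {self.delta:.4f}, df = {self.df}, p = {self.p:.4g}"


@dataclass
class CodonFitResult:
    """Maximum-likelihood fit of a (possibly clade-partitioned) codon model."""

    model_tag: str  # "M0" | "CLADES"
    lnl: float
    kappa: float
    omega: dict[int, float]
    branch_lengths: np.ndarray
    branch_labels: list[str]
    converged: bool
    n_iterations: int
    se: dict[str, float | None] = field(default_factory=dict)
    tree: Tree | None = None
    params: CodonModelParams | None = None
    n_sites: int = 0
    n_patterns: int = 0

    @property
    def n_free_parameters(self) -> int:
        return 1 + len(self.omega) + len(self.branch_lengths)

    def param_names(self) -> list[str]:
        return ["kappa"] + [f"omega{k}" for k in sorted(self.omega)]

    def compare_lr_test(self, null_result: "CodonFitResult", df: int | None = None) -> LRTResult:
        """LRT of this (alternative) fit against a nested null fit."""
        return likelihood_ratio_test(null_result, self, df=df)

    def summary(self) -> str:
        lines = [
            f"Codon model fit ({self.model_tag})",
            "=" * 46,
            f"log-likelihood      {self.lnl:.6f}",
            f"sites (patterns)    {self.n_sites} ({self.n_patterns})",
            f"converged           {self.converged} ({self.n_iterations} iterations)",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'std err':>14}",
        ]
        def fmt_se(name):
            se = self.se.get(name)
            return f"{se:>14.4f}" if se is not None else f"{'undefined':>14}"

        lines.append(f"{'kappa':<12}{self.kappa:>12.4f}{fmt_se('kappa')}")
        for k in sorted(self.omega):
            lines.append(f"{f'omega{k}':<12}{self.omega[k]:>12.4f}{fmt_se(f'omega{k}')}")
        lines.append("-" * 46)
        lines.append(f"tree length         {float(np.sum(self.branch_lengths)):.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_tag,
            "lnL": self.lnl,
            "kappa": self.kappa,
            "omega": {str(k): v for k, v in self.omega.items()},
            "se": self.se,
            "branch_lengths": dict(zip(self.branch_labels, map(float, self.branch_lengths))),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_sites": self.n_sites,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


class CladeDnDsModel:
    """dN/dS model for an alignment evolving on a partition-labelled tree.

    Parameters
    ----------
    aln
        Codon alignment; columns with gaps/ambiguities are dropped
        (complete-case) unless ``prefiltered=True``.
    tree
        Tree whose branch partition labels define the omega structure.
        With ``one_ratio=True`` the labels are ignored and a single omega
        is fitted (the M0 null model).
    frequencies
        ``"f3x4"`` (positional nucleotide products, default) or ``"f61"``
        (empirical codon frequencies).
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: Tree,
        *,
        one_ratio: bool = False,
        frequencies: str = "f3x4",
        code: GeneticCode = STANDARD_CODE,
        prefiltered: bool = False,
        stop_policy: str = "error",
    ) -> None:
        if not prefiltered:
            aln = filter_codon_columns(aln, stop_policy=stop_policy, code=code)
        self.aln = aln
        self.code = code
        self.one_ratio = one_ratio
        if frequencies == "f3x4":
            self.pi = f3x4_frequencies(aln, code)
        elif frequencies == "f61":
            self.pi = f61_frequencies(aln, code, pseudocount=0.5)
        else:
            raise ValueError(f"unknown frequency model {frequencies!r}")
        work = tree.copy()
        if one_ratio:
            for node in work.branches():
                node.partition = 0
        self.tree = work
        self.n_partitions = work.n_partitions()
        if not one_ratio and self.n_partitions < 2:
            raise ValueError(
                "clades model requires a foreground partition on the tree; "
                "pass one_ratio=True for the M0 model"
            )
        self.engine = PruningLikelihood(self.aln, self.tree, code)
        self.model_tag = "M0" if one_ratio else "CLADES"

    @classmethod
    def from_files(
        cls, alignment_path, tree_path, **kwargs
    ) -> "CladeDnDsModel":
        from .seqio import load_alignment
        from .trees import load_tree

        return cls(load_alignment(alignment_path), load_tree(tree_path), **kwargs)

    # ------------------------------------------------------------------ fitting
    def _params(self, kappa: float, omegas: np.ndarray) -> CodonModelParams:
        return CodonModelParams(
            kappa=float(kappa),
            omega_by_partition={k: float(omegas[k]) for k in range(self.n_partitions)},
            pi=self.pi,
        )

    def loglike(self, kappa: float, omegas, lengths=None) -> float:
        """Log-likelihood at explicit parameter values."""
        return self.engine.loglik(self._params(kappa, np.atleast_1d(omegas)), lengths)

    def _initial_lengths(self) -> np.ndarray:
        lengths = self.engine.branch_lengths()
        missing = ~np.isfinite(lengths) | (lengths <= 0)
        if missing.any():
            lengths = lengths.copy()
            lengths[missing] = max(self._mean_p_distance() / 2.0, 0.02)
        return np.clip(lengths, *BRANCH_BOUNDS)

    def _mean_p_distance(self) -> float:
        rows = self.aln.rows
        n = len(rows)
        if n < 2:
            return 0.05
        total, pairs = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                diff = sum(a != b for a, b in zip(rows[i], rows[j]))
                total += diff / len(rows[i])
                pairs += 1
        return total / pairs

    def fit(
        self,
        *,
        start: dict | None = None,
        multistart: int = 3,
        seed: int = 0,
        maxiter: int = 500,
        ftol: float = 1e-10,
        gtol: float = 1e-6,
        fix_kappa: float | None = None,
        tie_omegas: bool = False,
        compute_se: bool = True,
    ) -> CodonFitResult:
        """Maximize the likelihood over kappa, omegas and branch lengths.

        ``multistart`` random restarts (jittered in log-space, seeded) guard
        against flat starts; the best optimum is kept.  ``tie_omegas``
        constrains all partitions to a single omega (used to verify the
        nesting identity against the M0 fit).  ``fix_kappa`` holds kappa at
        a given value instead of estimating it.
        """
        K = 1 if tie_omegas else self.n_partitions
        n_branches = len(self.engine.branch_nodes)
        rng = np.random.default_rng(seed)

        start = start or {}
        kappa0 = float(start.get("kappa", 2.0)) if fix_kappa is None else fix_kappa
        omega0 = np.full(K, float(start.get("omega", 0.4)))
        lengths0 = np.asarray(start.get("lengths", self._initial_lengths()), float)

        lo = np.concatenate(
            [
                [np.log(KAPPA_BOUNDS[0])] if fix_kappa is None else [],
                np.full(K, np.log(OMEGA_BOUNDS[0])),
                np.full(n_branches, np.log(BRANCH_BOUNDS[0])),
            ]
        )
        hi = np.concatenate(
            [
                [np.log(KAPPA_BOUNDS[1])] if fix_kappa is None else [],
                np.full(K, np.log(OMEGA_BOUNDS[1])),
                np.full(n_branches, np.log(BRANCH_BOUNDS[1])),
            ]
        )
        n_kappa = 0 if fix_kappa is not None else 1

        def unpack(theta):
            if n_kappa:
                kappa, idx = np.exp(theta[0]), 1
            else:
                kappa, idx = fix_kappa, 0
            om = np.exp(theta[idx : idx + K])
            omegas = np.repeat(om, self.n_partitions) if K == 1 else om
            lengths = np.exp(theta[idx + K :])
            return kappa, om, omegas, lengths

        def objective(theta):
            kappa, om, omegas, lengths = unpack(theta)
            params = self._params(kappa, omegas)
            lnl, branch_grad = self.engine.loglik_and_branch_grad(params, lengths)
            grad = np.empty_like(theta)
            idx = n_kappa + K
            grad[idx:] = -branch_grad * lengths  # d/d log t
            # central finite differences for kappa / omegas on the log scale
            h = 1e-5
            for pos in range(idx):
                tp, tm = theta.copy(), theta.copy()
                tp[pos] += h
                tm[pos] -= h
                kp, _, omp, _ = unpack(tp)
                km, _, omm, _ = unpack(tm)
                lp = self.engine.loglik(self._params(kp, omp), lengths)
                lm = self.engine.loglik(self._params(km, omm), lengths)
                grad[pos] = -(lp - lm) / (2 * h)
            return -lnl, grad

        base_theta = np.concatenate(
            [
                [np.log(kappa0)] if n_kappa else [],
                np.log(np.clip(omega0, *OMEGA_BOUNDS)),
                np.log(lengths0),
            ]
        )
        best = None
        total_iter = 0
        for trial in range(max(1, multistart)):
            theta0 = base_theta.copy()
            if trial > 0:
                theta0 = theta0 + rng.uniform(-0.7, 0.7, size=theta0.shape)
            theta0 = np.clip(theta0, lo, hi)
            res = optimize.minimize(
                objective,
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
            )
            total_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res

        kappa_hat, om_hat, omegas_full, lengths_hat = unpack(best.x)
        omega_map = (
            {k: float(om_hat[0]) for k in range(self.n_partitions)}
            if K == 1
            else {k: float(om_hat[k]) for k in range(self.n_partitions)}
        )
        fitted_tree = self.tree.copy()
        for node, t in zip(
            [n for n in fitted_tree.postorder() if n.parent is not None], lengths_hat
        ):
            node.length = float(t)
        params = self._params(kappa_hat, omegas_full)
        labels = [
            n.name or f"node{i}" for i, n in enumerate(self.engine.branch_nodes)
        ]
        result = CodonFitResult(
            model_tag="M0" if (self.one_ratio or tie_omegas) else self.model_tag,
            lnl=-float(best.fun),
            kappa=float(kappa_hat),
            omega=omega_map if not tie_omegas else {0: float(om_hat[0])},
            branch_lengths=lengths_hat,
            branch_labels=labels,
            converged=bool(best.success),
            n_iterations=int(total_iter),
            tree=fitted_tree,
            params=params,
            n_sites=self.engine.n_sites,
            n_patterns=self.engine.n_patterns,
        )
        if compute_se:
            result.se = self._standard_errors(
                result, fix_kappa=fix_kappa, tie_omegas=tie_omegas
            )
        return result

    # ------------------------------------------------------------------ errors
    def _standard_errors(
        self,
        result: CodonFitResult,
        *,
        fix_kappa: float | None = None,
        tie_omegas: bool = False,
    ) -> dict[str, float | None]:
        """Wald standard errors from the observed information in (kappa, omegas).

        Central finite-difference Hessian of lnL at the MLE with branch
        lengths held at their estimates.  An SE is reported as undefined
        (``None``) when the estimate sits at a bound or the information
        matrix is not positive definite.
        """
        K = 1 if tie_omegas else self.n_partitions
        names, values, bounds = [], [], []
        if fix_kappa is None:
            names.append("kappa")
            values.append(result.kappa)
            bounds.append(KAPPA_BOUNDS)
        for k in range(K):
            names.append(f"omega{k}")
            values.append(result.omega[k if not tie_omegas else 0])
            bounds.append(OMEGA_BOUNDS)
        values = np.array(values)
        lengths = result.branch_lengths

        at_bound = np.array(
            [
                v <= lo * (1 + _BOUNDARY_RTOL) or v >= hi * (1 - _BOUNDARY_RTOL)
                for v, (lo, hi) in zip(values, bounds)
            ]
        )
        free = ~at_bound
        se: dict[str, float | None] = {name: None for name in names}
        if not free.any():
            return se

        free_idx = np.where(free)[0]

        def lnl_at(v):
            full = values.copy()
            full[free_idx] = v
            kappa = full[0] if fix_kappa is None else fix_kappa
            om = full[1:] if fix_kappa is None else full
            omegas = np.repeat(om, self.n_partitions) if K == 1 else om
            return self.engine.loglik(self._params(kappa, omegas), lengths)

        x0 = values[free_idx]
        m = len(x0)
        h = np.maximum(1e-4, 1e-3 * np.abs(x0))
        H = np.empty((m, m))
        f0 = lnl_at(x0)
        for a in range(m):
            for b in range(a, m):
                if a == b:
                    xp, xm = x0.copy(), x0.copy()
                    xp[a] += h[a]
                    xm[a] -= h[a]
                    H[a, a] = (lnl_at(xp) - 2 * f0 + lnl_at(xm)) / h[a] ** 2
                else:
                    xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                    xpp[[a, b]] += [h[a], h[b]]
                    xpm[a] += h[a]
                    xpm[b] -= h[b]
                    xmp[a] -= h[a]
                    xmp[b] += h[b]
                    xmm[[a, b]] -= [h[a], h[b]]
                    H[a, b] = H[b, a] = (
                        lnl_at(xpp) - lnl_at(xpm) - lnl_at(xmp) + lnl_at(xmm)
                    ) / (4 * h[a] * h[b])
        info = -H
        if not np.all(np.isfinite(info)):
            raise FloatingPointError("non-finite entries in the observed information")
        try:
            eigvals = np.linalg.eigvalsh(info)
            if eigvals.min() <= 0:
                return se
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return se
        for pos, idx in enumerate(free_idx):
            var = cov[pos, pos]
            se[names[idx]] = float(np.sqrt(var)) if var > 0 else None
        return se


# ---------------------------------------------------------------------- API
def fit_m0(aln: CodonAlignment, tree: Tree, **opts) -> CodonFitResult:
    """Fit the one-ratio M0 model (single omega for the whole tree)."""
    model_kw = {k: opts.pop(k) for k in ("frequencies", "code", "prefiltered", "stop_policy") if k in opts}
    return CladeDnDsModel(aln, tree, one_ratio=True, **model_kw).fit(**opts)


def fit_clades(aln: CodonAlignment, tree: Tree, **opts) -> CodonFitResult:
    """Fit the clades model (background omega1, foreground omega2)."""
    model_kw = {k: opts.pop(k) for k in ("frequencies", "code", "prefiltered", "stop_policy") if k in opts}
    return CladeDnDsModel(aln, tree, one_ratio=False, **model_kw).fit(**opts)


def standard_errors(
    fit: CodonFitResult, aln: CodonAlignment, tree: Tree, **model_kw
) -> CodonFitResult:
    """Recompute Wald standard errors for an existing fit (returns the fit)."""
    model = CladeDnDsModel(aln, tree, one_ratio=fit.model_tag == "M0", **model_kw)
    fit.se = model._standard_errors(fit)
    return fit


def likelihood_ratio_test(
    null_fit: CodonFitResult, alt_fit: CodonFitResult, df: int | None = None
) -> LRTResult:
    """Chi-square LRT of nested fits: delta = 2(lnL_alt - lnL_null).

    Small negative deltas (optimizer tolerance) are clamped to zero; a
    delta below -1e-6 indicates the models are not nested or one fit did
    not converge and raises.
    """
    if df is None:
        df = len(alt_fit.omega) - len(null_fit.omega)
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    delta = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if delta < -1e-6:
        raise ValueError(
            f"alternative log-likelihood is below the null ({delta=}); "
            "models are not nested or optimization failed"
        )
    delta = max(delta, 0.0)
    return LRTResult(delta=delta, df=int(df), p=float(chi2.sf(delta, df)))
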