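"""Maximum-likelihood fitting of M0 and branch-site models, and the LRT.

Optimisation is bounded quasi-Newton (L-BFGS-B) on transformed parameters:
log scale for omega and kappa, ``1 + exp`` for omega2 (so the alternative
model respects omega2 >= 1), logit for omega0 and a softmax over
(p0, p1, rest) for the mixture proportions.  Gradients are finite
differences.  Branch-site fits are multi-started from three fixed points
because the mixture surface is multi-modal; the best of the starts is kept.

The test for positive selection compares the alternative branch-site model
(omega2 free) against the null (omega2 = 1) with twice the log-likelihood
ratio referred to chi-square with one degree of freedom (the convention of
codeml-style software; the null value of omega2 sits on the boundary, which
makes the test conservative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .codon_space import CodonSpace, build_codon_space
from .likelihood import (
    Alignment,
    PruningEngine,
    Tree,
    branch_site_system,
    m0_system,
)
from .substitution_models import BranchSiteParams, M0Params

M0_BOUNDS = {"omega": (1e-4, 50.0), "kappa": (1e-2, 100.0)}
BRANCH_LENGTH_BOUNDS = (1e-8, 50.0)
OMEGA2_MAX = 999.0

#: Fixed branch-site starting points (omega0, omega2, p0, p1).
BS_STARTS = (
    (0.1, 2.0, 0.7, 0.2),
    (0.5, 5.0, 0.4, 0.4),
    (0.9, 1.5, 0.2, 0.6),
)
_KAPPA_START = 2.0
_LOGIT_CAP = 12.0


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: str
    strategy: str
    estimates: dict[str, float]
    lnL: float
    n_function_evaluations: int
    converged: bool
    seed: int
    branch_lengths: dict[int, float] | None = None


@dataclass
class LRTResult:
    """Likelihood ratio test: 2(lnL_alt - lnL_null) vs chi-square(1)."""

    lnL_null: float
    lnL_alt: float
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


class _CountedObjective:
    def __init__(self, fn):
        self.fn = fn
        self.n_evals = 0

    def __call__(self, x):
        self.n_evals += 1
        val = self.fn(x)
        if not np.isfinite(val):
            return 1e12
        return val


def fit_m0(
    alignment: Alignment,
    tree: Tree,
    strategy: str = "none",
    optimize_branch_lengths: bool = False,
    seed: int = 0,
    pi: np.ndarray | None = None,
    space: CodonSpace | None = None,
    max_evals: int | None = None,
    start: tuple[float, float] = (1.0, 2.0),
) -> FitResult:
    """Fit M0 by maximising over omega and kappa (optionally branch lengths).

    Branch lengths are held at the tree's values unless
    ``optimize_branch_lengths`` is set, in which case each branch length is
    a free (log-scale) parameter.  ``pi`` defaults to equal codon
    frequencies.
    """
    space = space or build_codon_space()
    if pi is None:
        pi = np.full(space.n_states, 1.0 / space.n_states)
    engine = PruningEngine(alignment, tree, strategy=strategy, seed=seed, space=space)
    edges = tree.edges
    base_lengths = [tree.nodes[e].length for e in edges]

    def unpack(x):
        omega, kappa = np.exp(x[0]), np.exp(x[1])
        if optimize_branch_lengths:
            for e, le in zip(edges, np.exp(x[2:])):
                tree.nodes[e].length = float(le)
        return M0Params(omega=omega, kappa=kappa, pi=pi)

    def negloglik(x):
        params = unpack(x)
        return -engine.loglik(*m0_system(tree, params, space))

    obj = _CountedObjective(negloglik)
    x0 = [np.log(start[0]), np.log(start[1])]
    bounds = [tuple(np.log(M0_BOUNDS["omega"])), tuple(np.log(M0_BOUNDS["kappa"]))]
    if optimize_branch_lengths:
        x0 += [np.log(max(t, 1e-6)) for t in base_lengths]
        bounds += [tuple(np.log(BRANCH_LENGTH_BOUNDS))] * len(edges)
    options = {"ftol": 1e-10, "gtol": 1e-6, "maxiter": 500}
    if max_evals is not None:
        options["maxfun"] = max_evals
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds, options=options)
    params = unpack(res.x)
    branch_lengths = None
    if optimize_branch_lengths:
        branch_lengths = {e: tree.nodes[e].length for e in edges}
    else:
        for e, t in zip(edges, base_lengths):
            tree.nodes[e].length = t
    return FitResult(
        model="M0",
        strategy=strategy,
        estimates={"omega": params.omega, "kappa": params.kappa},
        lnL=-float(res.fun),
        n_function_evaluations=obj.n_evals,
        converged=bool(res.success),
        seed=seed,
        branch_lengths=branch_lengths,
    )


def _bs_pack(omega0, omega2, p0, p1, kappa, null):
    x = [
        _logit(omega0),
        np.log(kappa),
        np.log(p0),
        np.log(p1),
    ]
    # proportions via softmax over (p0, p1, rest): free logits for p0, p1
    rest = max(1.0 - p0 - p1, 1e-9)
    x[2] = np.log(p0 / rest)
    x[3] = np.log(p1 / rest)
    if not null:
        x.append(np.log(max(omega2 - 1.0, 1e-6)))
    return np.array(x)


def _bs_unpack(x, null, pi):
    omega0 = _expit(x[0])
    kappa = float(np.exp(x[1]))
    z0, z1 = x[2], x[3]
    denom = 1.0 + np.exp(z0) + np.exp(z1)
    p0 = float(np.exp(z0) / denom)
    p1 = float(np.exp(z1) / denom)
    omega2 = 1.0 if null else float(1.0 + np.exp(x[4]))
    return BranchSiteParams(
        omega0=omega0, omega2=min(omega2, OMEGA2_MAX), p0=p0, p1=p1, kappa=kappa, pi=pi
    )


def fit_branch_site(
    alignment: Alignment,
    tree: Tree,
    hypothesis: str = "alternative",
    strategy: str = "none",
    seed: int = 0,
    pi: np.ndarray | None = None,
    space: CodonSpace | None = None,
    max_evals: int | None = None,
    starts: tuple = BS_STARTS,
    max_iter_per_start: int = 200,
) -> FitResult:
    """Fit the branch-site model (null fixes omega2 = 1).

    Multi-started from the fixed points in ``starts``; the best final
    likelihood wins.  Requires one flagged foreground branch.
    """
    if hypothesis not in ("null", "alternative"):
        raise ValueError(f"hypothesis must be 'null' or 'alternative', got {hypothesis!r}")
    if not tree.foreground_edges:
        raise ValueError("branch-site model requires a flagged foreground branch")
    space = space or build_codon_space()
    if pi is None:
        pi = np.full(space.n_states, 1.0 / space.n_states)
    null = hypothesis == "null"
    engine = PruningEngine(alignment, tree, strategy=strategy, seed=seed, space=space)

    def negloglik(x):
        params = _bs_unpack(x, null, pi)
        return -engine.loglik(*branch_site_system(tree, params, space))

    n_free = 4 if null else 5
    bounds = [(-_LOGIT_CAP, _LOGIT_CAP), tuple(np.log(M0_BOUNDS["kappa"]))] + [
        (-_LOGIT_CAP, _LOGIT_CAP)
    ] * 2
    if not null:
        bounds.append((-_LOGIT_CAP, float(np.log(OMEGA2_MAX - 1.0))))

    obj = _CountedObjective(negloglik)
    # two-stage multistart: a short exploratory run from each fixed start,
    # then one full-length polish from the best exploratory endpoint
    best = None
    explore_iter = min(20, max_iter_per_start)
    for omega0, omega2, p0, p1 in starts:
        x0 = _bs_pack(omega0, omega2, p0, p1, _KAPPA_START, null)[:n_free]
        options = {"ftol": 1e-10, "gtol": 1e-6, "maxiter": explore_iter}
        if max_evals is not None:
            options["maxfun"] = max(max_evals - obj.n_evals, 1)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds, options=options)
        if best is None or res.fun < best.fun:
            best = res
        if max_evals is not None and obj.n_evals >= max_evals:
            break
    options = {"ftol": 1e-10, "gtol": 1e-6, "maxiter": max_iter_per_start}
    if max_evals is not None:
        options["maxfun"] = max(max_evals - obj.n_evals, 1)
    polished = optimize.minimize(
        obj, best.x, method="L-BFGS-B", bounds=bounds, options=options
    )
    any_converged = bool(polished.success)
    if polished.fun <= best.fun:
        best = polished
    params = _bs_unpack(best.x, null, pi)
    estimates = {
        "omega0": params.omega0,
        "omega2": params.omega2,
        "p0": params.p0,
        "p1": params.p1,
        "kappa": params.kappa,
    }
    return FitResult(
        model="branch-site-null" if null else "branch-site-alternative",
        strategy=strategy,
        estimates=estimates,
        lnL=-float(best.fun),
        n_function_evaluations=obj.n_evals,
        converged=any_converged,
        seed=seed,
    )


def lrt(null: FitResult, alt: FitResult, alpha: float = 0.05) -> LRTResult:
    """Likelihood ratio test of the alternative against the nested null."""
    delta = 2.0 * (alt.lnL - null.lnL)
    if delta < -1e-6:
        warnings.warn(
            f"alternative lnL ({alt.lnL:.6f}) below null lnL ({null.lnL:.6f}); "
            "optimization may not have converged",
            RuntimeWarning,
            stacklevel=2,
        )
    statistic = max(0.0, delta)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return LRTResult(
        lnL_null=null.lnL,
        lnL_alt=alt.lnL,
        statistic=statistic,
        p_value=p_value,
        significant=p_value < alpha,
        alpha=alpha,
    )


def test_positive_selection(
    alignment: Alignment,
    tree: Tree,
    strategy: str = "none",
    alpha: float = 0.05,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[LRTResult, FitResult, FitResult]:
    """Convenience wrapper: fit both hypotheses and run the LRT."""
    null = fit_branch_site(
        alignment, tree, hypothesis="null", strategy=strategy, seed=seed, **fit_kwargs
    )
    alt = fit_branch_site(
        alignment, tree, hypothesis="alternative", strategy=strategy, seed=seed, **fit_kwargs
    )
    return lrt(null, alt, alpha=alpha), null, alt
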