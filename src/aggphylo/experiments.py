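"""Scaled simulation studies and the analytic cost model of aggregation.

Wall-clock benchmarking is deliberately replaced by an analytic timing
model: with per-operation unit costs, a full likelihood evaluation costs

    T_full = t_eigen + K t_exp + N K 61 t_prun

and an aggregated evaluation

    T_aggr = t_eigen + K t_exp + N K t_agg + N K M t_prun

(N alignment positions, K internal nodes, M states after aggregation, 61
states before).  Their ratio is the predicted speedup; eigendecomposition
is unaffected by aggregation, which is why the speedup grows with N and
shrinks as M grows.  Observed speedups are hardware- and
implementation-dependent, so this package validates the monotone
relationships on the cost model rather than on timed runs.

The experiment drivers rerun the accuracy/consistency study at reduced
scale: replicate branch-site datasets are simulated, fitted in full and
aggregated modes, and compared through parameter correlations, LRT
decision cross-tables and ROC/AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

from .aggregation import observed_states
from .codon_space import build_codon_space
from .inference import fit_branch_site, lrt
from .likelihood import Alignment
from .simulate import (
    choose_foreground_branch,
    sample_branch_site_parameters,
    simulate_alignment,
    simulate_birth_death_tree,
)

N_CODON_STATES = 61


@dataclass(frozen=True)
class TimingModel:
    """Abstract unit costs of the likelihood pipeline."""

    t_eigen: float
    t_exp: float
    t_prun: float
    t_agg: float
    N: int
    K: int
    M: float
    n_states: int = N_CODON_STATES

    def __post_init__(self) -> None:
        if min(self.t_eigen, self.t_exp, self.t_prun, self.t_agg) < 0:
            raise ValueError("unit costs must be nonnegative")
        if not 1 <= self.M <= self.n_states:
            raise ValueError(f"M must lie in [1, {self.n_states}]")

    @property
    def t_full(self) -> float:
        return self.t_eigen + self.K * self.t_exp + self.N * self.K * self.n_states * self.t_prun

    @property
    def t_aggr(self) -> float:
        return (
            self.t_eigen
            + self.K * self.t_exp
            + self.N * self.K * self.t_agg
            + self.N * self.K * self.M * self.t_prun
        )


@dataclass
class ExperimentReport:
    """Per-replicate table plus summary statistics of one study."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def predicted_speedup(tm: TimingModel, include_exp: bool = False) -> float:
    """Predicted aggregation speedup from the cost model.

    By default uses the eigendecomposition+pruning approximation (matrix
    exponentiation drops out); ``include_exp=True`` evaluates the full
    T_full / T_aggr ratio.
    """
    if include_exp:
        num, den = tm.t_full, tm.t_aggr
    else:
        num = tm.t_eigen + tm.N * tm.K * tm.n_states * tm.t_prun
        den = tm.t_eigen + tm.N * tm.K * tm.t_agg + tm.N * tm.K * tm.M * tm.t_prun
    if den <= 0:
        raise ZeroDivisionError("cost model denominator is zero")
    return num / den


def observed_codon_summary(alignment: Alignment) -> tuple[np.ndarray, float]:
    """Per-site aggregated state counts M and their mean.

    M at a site is the observed codon count plus one meta-state, capped at
    61 (a site where everything is observed cannot be aggregated).
    """
    space = build_codon_space()
    m_values = np.array(
        [
            min(len(observed_states(alignment, s, space)) + 1, N_CODON_STATES)
            for s in range(alignment.n_sites)
        ]
    )
    return m_values, float(m_values.mean())


def _simulate_replicate(seed: int, hypothesis: str | None, ranges):
    design = sample_branch_site_parameters(seed, hypothesis=hypothesis, ranges=ranges)
    tree = simulate_birth_death_tree(
        design.n_tips, target_tree_length=design.tree_length, seed=seed
    )
    choose_foreground_branch(tree, seed)
    aln = simulate_alignment(tree, design.params, design.n_sites, seed=seed)
    return design, tree, aln


def _fit_both_modes(aln, tree, strategy, alpha, seed, fit_kwargs):
    out = {}
    for mode, strat in (("full", "none"), ("aggregated", strategy)):
        null = fit_branch_site(
            aln, tree, hypothesis="null", strategy=strat, seed=seed, **fit_kwargs
        )
        alt = fit_branch_site(
            aln, tree, hypothesis="alternative", strategy=strat, seed=seed, **fit_kwargs
        )
        out[mode] = (null, alt, lrt(null, alt, alpha=alpha))
    return out


def run_correlation_experiment(
    n_replicates: int,
    strategy: str = "full",
    seed: int = 0,
    alpha: float = 0.05,
    ranges: Mapping | None = None,
    fit_kwargs: Mapping | None = None,
) -> ExperimentReport:
    """Between-mode parameter correlations on alternative-model fits.

    Simulates ``n_replicates`` branch-site datasets (half null, half
    alternative), fits the alternative hypothesis in full and aggregated
    modes and reports Pearson correlations between the two modes (and
    against truth) for omega0, kappa, p0, p1 and omega2 (omega2 over
    alternative replicates only).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    for i in range(n_replicates):
        rep_seed = seed * 1_000_003 + i
        design, tree, aln = _simulate_replicate(rep_seed, None, ranges)
        fits = _fit_both_modes(aln, tree, strategy, alpha, rep_seed, fit_kwargs)
        row = {
            "replicate": i,
            "hypothesis": design.hypothesis,
            "n_sites": design.n_sites,
            "n_tips": design.n_tips,
            "tree_length": design.tree_length,
        }
        for name, value in (
            ("omega0", design.params.omega0),
            ("omega2", design.params.omega2),
            ("p0", design.params.p0),
            ("p1", design.params.p1),
            ("kappa", design.params.kappa),
        ):
            row[f"true_{name}"] = value
        for mode in ("full", "aggregated"):
            _, alt, test = fits[mode]
            for name, value in alt.estimates.items():
                row[f"{mode}_{name}"] = value
            row[f"{mode}_lrt"] = test.statistic
            row[f"{mode}_significant"] = test.significant
        rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    alt_mask = table["hypothesis"] == "alternative"
    for name in ("omega0", "kappa", "p0", "p1", "omega2"):
        sub = table[alt_mask] if name == "omega2" else table
        if len(sub) >= 2:
            summary[f"corr_{name}"] = float(
                np.corrcoef(sub[f"full_{name}"], sub[f"aggregated_{name}"])[0, 1]
            )
            summary[f"corr_truth_{name}"] = float(
                np.corrcoef(sub[f"true_{name}"], sub[f"full_{name}"])[0, 1]
            )
    return ExperimentReport(table=table, summary=summary)


def run_consistency_experiment(
    n_null: int,
    n_alt: int,
    strategy: str = "full",
    alpha: float = 0.05,
    seed: int = 0,
    ranges: Mapping | None = None,
    fit_kwargs: Mapping | None = None,
) -> ExperimentReport:
    """LRT decision agreement between full and aggregated modes.

    Emits per-mode confusion counts (TP/TN/FP/FN against the simulated
    truth), the 2x2 full-vs-aggregated decision cross-tables separately for
    null and alternative replicates, the overall agreement fraction, and
    ROC/AUC over the LRT statistic.
    """
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    for i in range(n_null + n_alt):
        hypothesis = "null" if i < n_null else "alternative"
        rep_seed = seed * 1_000_003 + i
        design, tree, aln = _simulate_replicate(rep_seed, hypothesis, ranges)
        fits = _fit_both_modes(aln, tree, strategy, alpha, rep_seed, fit_kwargs)
        row = {
            "replicate": i,
            "hypothesis": hypothesis,
            "true_omega2": design.params.omega2,
        }
        for mode in ("full", "aggregated"):
            _, _, test = fits[mode]
            row[f"{mode}_lrt"] = test.statistic
            row[f"{mode}_p"] = test.p_value
            row[f"{mode}_significant"] = bool(test.significant)
        rows.append(row)
    table = pd.DataFrame(rows)
    truth = (table["hypothesis"] == "alternative").to_numpy()
    summary: dict = {"alpha": alpha, "n_null": n_null, "n_alt": n_alt}
    for mode in ("full", "aggregated"):
        sig = table[f"{mode}_significant"].to_numpy()
        summary[f"{mode}_tp"] = int(np.sum(sig & truth))
        summary[f"{mode}_tn"] = int(np.sum(~sig & ~truth))
        summary[f"{mode}_fp"] = int(np.sum(sig & ~truth))
        summary[f"{mode}_fn"] = int(np.sum(~sig & truth))
        if n_null:
            summary[f"{mode}_type1_rate"] = float(np.mean(sig[~truth]))
        if n_alt:
            summary[f"{mode}_power"] = float(np.mean(sig[truth]))
        if n_null and n_alt:
            summary[f"{mode}_auc"] = float(
                _skmetrics.roc_auc_score(truth, table[f"{mode}_lrt"])
            )
    agree = table["full_significant"].to_numpy() == table["aggregated_significant"].to_numpy()
    summary["agreement_fraction"] = float(np.mean(agree))
    for label, mask in (("null", ~truth), ("alt", truth)):
        if mask.any():
            f = table["full_significant"].to_numpy()[mask]
            a = table["aggregated_significant"].to_numpy()[mask]
            summary[f"crosstab_{label}"] = {
                "full-_agg-": int(np.sum(~f & ~a)),
                "full-_agg+": int(np.sum(~f & a)),
                "full+_agg-": int(np.sum(f & ~a)),
                "full+_agg+": int(np.sum(f & a)),
            }
    return ExperimentReport(table=table, summary=summary)
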