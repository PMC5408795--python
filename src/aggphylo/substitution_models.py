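"""GY94-style codon rate matrices, eigendecomposition and P(t).

Implements the M0 (one-ratio) model and the branch-site model's per-class
rate matrices.  Rates follow the Goldman-Yang parameterisation: a single
nucleotide change from codon *i* to codon *j* has rate

    q_ij = pi_j * kappa^{transition} * omega^{nonsynonymous}

with all multi-nucleotide changes forbidden (rate 0).  Each matrix is
rescaled so the expected number of substitutions per codon per unit branch
length is one (``-sum_i pi_i q_ii = 1``), the convention used by codeml-like
software for branch-length units.

Matrix exponentials use the symmetric similarity transform
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is symmetric for any
time-reversible generator and therefore has a real spectrum; ``P(t)`` is then
``U exp(Lambda t) U^{-1}`` from a single eigendecomposition per Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .codon_space import CodonSpace, SubstitutionClass, classify_substitution

if TYPE_CHECKING:  # pragma: no cover
    from .likelihood import Alignment

_FREQ_TOL = 1e-12


@dataclass(frozen=True)
class M0Params:
    """One-ratio model parameters: omega (dN/dS), kappa (ts/tv), pi (61 freqs)."""

    omega: float
    kappa: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if pi.shape != (61,) or np.any(pi < 0):
            raise ValueError("pi must be 61 nonnegative frequencies")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")


#: Site classes of the branch-site model, in fixed order.
SITE_CLASSES = ("0", "1", "2a", "2b")
BRANCH_TYPES = ("background", "foreground")


@dataclass(frozen=True)
class BranchSiteParams:
    """Branch-site model A parameters.

    Four site classes: class 0 evolves under ``omega0 <= 1`` everywhere;
    class 1 under ``omega1 = 1`` everywhere; classes 2a/2b switch to
    ``omega2 >= 1`` on the foreground branch while keeping omega0 / 1 on
    background branches.  Mixture proportions follow the standard
    construction from (p0, p1).
    """

    omega0: float
    omega2: float
    p0: float
    p1: float
    kappa: float
    pi: np.ndarray
    omega1: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        if not 0.0 <= self.omega0 <= 1.0:
            raise ValueError("omega0 must lie in [0, 1]")
        if self.omega2 < 1.0:
            raise ValueError("omega2 must be >= 1")
        if not (self.p0 > 0 and self.p1 > 0 and self.p0 + self.p1 <= 1.0 + _FREQ_TOL):
            raise ValueError("need p0, p1 > 0 with p0 + p1 <= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def p2a(self) -> float:
        return (1.0 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1.0 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        """Class proportions (p0, p1, p2a, p2b); sums to 1."""
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    def class_omega(self, site_class: str, branch_type: str) -> float:
        """The dN/dS ratio acting on a site class along a branch type."""
        if site_class == "0":
            return self.omega0
        if site_class == "1":
            return self.omega1
        if site_class in ("2a", "2b"):
            if branch_type == "foreground":
                return self.omega2
            return self.omega0 if site_class == "2a" else self.omega1
        raise ValueError(f"unknown site class {site_class!r}")


@dataclass(frozen=True)
class RateMatrix:
    """An instantaneous rate matrix Q with its stationary frequencies."""

    Q: np.ndarray
    pi: np.ndarray


@dataclass(frozen=True)
class Eigensystem:
    """Q = U diag(Lambda) U^{-1}; Lambda is real for reversible generators."""

    U: np.ndarray
    Lambda: np.ndarray
    U_inv: np.ndarray


@dataclass(frozen=True)
class TransitionMatrix:
    """P(t) = e^{Qt}: rows sum to one, entries clamped into [0, 1]."""

    P: np.ndarray
    t: float


def equilibrium_frequencies(
    mode: str, alignment: "Alignment | None" = None, space: CodonSpace | None = None
) -> np.ndarray:
    """Codon equilibrium frequencies.

    ``equal``: 1/61 each.  ``empirical``: observed codon counts with add-one
    smoothing, renormalised.  ``f3x4``: products of per-codon-position
    nucleotide frequencies with stop codons removed and renormalised.
    """
    from .codon_space import build_codon_space

    if space is None:
        space = build_codon_space()
    n = space.n_states
    if mode == "equal":
        return np.full(n, 1.0 / n)
    if alignment is None or not alignment.sequences:
        raise ValueError(f"mode {mode!r} requires a non-empty alignment")
    if mode == "empirical":
        counts = np.ones(n)  # add-one smoothing
        for seq in alignment.sequences:
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                idx = space.index.get(codon)
                if idx is not None:
                    counts[idx] += 1
        return counts / counts.sum()
    if mode == "f3x4":
        pos_counts = np.zeros((3, 4))
        nuc_index = {b: k for k, b in enumerate("ACGT")}
        for seq in alignment.sequences:
            for i, base in enumerate(seq):
                k = nuc_index.get(base)
                if k is not None:
                    pos_counts[i % 3, k] += 1
        if np.any(pos_counts.sum(axis=1) == 0):
            raise ValueError("f3x4 requires observed nucleotides at all positions")
        pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        freqs = np.array(
            [
                pos_freqs[0, nuc_index[c[0]]]
                * pos_freqs[1, nuc_index[c[1]]]
                * pos_freqs[2, nuc_index[c[2]]]
                for c in space.codons
            ]
        )
        total = freqs.sum()
        if total <= 0:
            raise ValueError("degenerate f3x4 frequencies")
        return freqs / total
    raise ValueError(f"unknown frequency mode {mode!r}")


_MASK_CACHE: dict[tuple[str, ...], dict[SubstitutionClass, np.ndarray]] = {}


def substitution_class_masks(space: CodonSpace) -> dict[SubstitutionClass, np.ndarray]:
    """Boolean 61x61 masks per substitution class (cached per codon space)."""
    key = space.codons
    if key not in _MASK_CACHE:
        n = space.n_states
        masks = {cls: np.zeros((n, n), dtype=bool) for cls in SubstitutionClass}
        for i, ci in enumerate(space.codons):
            for j, cj in enumerate(space.codons):
                masks[classify_substitution(ci, cj, space)][i, j] = True
        _MASK_CACHE[key] = masks
    return _MASK_CACHE[key]


def _substitution_multipliers(space: CodonSpace, omega: float, kappa: float) -> np.ndarray:
    """61x61 matrix of kappa/omega factors (0 for multiple/identical)."""
    masks = substitution_class_masks(space)
    mult = np.zeros((space.n_states, space.n_states))
    mult[masks[SubstitutionClass.SYNONYMOUS_TRANSVERSION]] = 1.0
    mult[masks[SubstitutionClass.SYNONYMOUS_TRANSITION]] = kappa
    mult[masks[SubstitutionClass.NONSYNONYMOUS_TRANSVERSION]] = omega
    mult[masks[SubstitutionClass.NONSYNONYMOUS_TRANSITION]] = omega * kappa
    return mult


def _assemble_rate_matrix(mult: np.ndarray, pi: np.ndarray) -> np.ndarray:
    Q = mult * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix: zero mean substitution rate")
    return Q / mean_rate


def build_m0_rate_matrix(params: M0Params, space: CodonSpace) -> RateMatrix:
    """GY94 M0 rate matrix, normalised to one expected substitution per codon."""
    pi = params.pi
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1")
    mult = _substitution_multipliers(space, params.omega, params.kappa)
    return RateMatrix(Q=_assemble_rate_matrix(mult, pi), pi=pi)


def gy94_mean_rate(omega: float, kappa: float, pi: np.ndarray, space: CodonSpace) -> float:
    """Mean substitution rate of the *unnormalised* GY94 generator."""
    mult = _substitution_multipliers(space, omega, kappa)
    Q = mult * pi[np.newaxis, :]
    return float((pi[:, None] * Q).sum())


def branch_site_rate_multipliers(
    params: BranchSiteParams, space: CodonSpace
) -> dict[float, float]:
    """Relative rate of each omega class under the shared model scale.

    All branch-site class matrices share one scale factor so that branch
    lengths are expected substitutions per codon averaged over the site
    classes on background branches.  A class with omega value w then runs
    at relative rate mu(w) / f, where mu is the unnormalised GY94 mean rate
    and f = (p0 + p2a) mu(omega0) + (p1 + p2b) mu(1).  Rescaling every
    class to rate one instead would make omega2 almost unidentifiable: the
    only remaining signature of positive selection would be the
    substitution *composition* on the foreground branch, which a null
    mixture reproduces almost exactly.
    """
    mus = {
        omega: gy94_mean_rate(omega, params.kappa, params.pi, space)
        for omega in {params.omega0, params.omega1, params.omega2}
    }
    f = (params.p0 + params.p2a) * mus[params.omega0] + (params.p1 + params.p2b) * mus[
        params.omega1
    ]
    if f <= 0:
        raise ValueError("degenerate branch-site scaling: zero background rate")
    return {omega: mu / f for omega, mu in mus.items()}


def build_branch_site_matrices(
    params: BranchSiteParams, space: CodonSpace
) -> dict[tuple[str, str], RateMatrix]:
    """Per (site-class, branch-type) rate matrices of the branch-site model.

    Matrices sharing an omega are the same object; all share the common
    scale of `branch_site_rate_multipliers` (the background-mixture mean
    rate is one).
    """
    multipliers = branch_site_rate_multipliers(params, space)
    by_omega: dict[float, RateMatrix] = {}
    out: dict[tuple[str, str], RateMatrix] = {}
    for site_class in SITE_CLASSES:
        for branch_type in BRANCH_TYPES:
            omega = params.class_omega(site_class, branch_type)
            if omega not in by_omega:
                base = build_m0_rate_matrix(
                    M0Params(omega=omega, kappa=params.kappa, pi=params.pi), space
                )
                by_omega[omega] = RateMatrix(Q=base.Q * multipliers[omega], pi=base.pi)
            out[(site_class, branch_type)] = by_omega[omega]
    return out


def eigendecompose(rm: RateMatrix) -> Eigensystem:
    """Eigendecompose a reversible Q via the symmetric similarity transform.

    ``S = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is symmetric when detailed
    balance holds, so its spectrum is real and `numpy.linalg.eigh` applies.
    """
    pi = rm.pi
    if np.any(pi <= 0):
        raise ValueError("degenerate transform: zero stationary frequency")
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * rm.Q / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)  # symmetrise away float noise
    lam, V = np.linalg.eigh(S)
    U = V / sqrt_pi[:, None]
    U_inv = V.T * sqrt_pi[None, :]
    return Eigensystem(U=U, Lambda=lam, U_inv=U_inv)


def transition_matrix(es: Eigensystem, t: float) -> TransitionMatrix:
    """P(t) = U exp(Lambda t) U^{-1}, clamped into [0,1] and row-normalised."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    P = (es.U * np.exp(es.Lambda * t)[None, :]) @ es.U_inv
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P=P, t=t)
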