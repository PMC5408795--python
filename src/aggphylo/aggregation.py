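"""Markov-state aggregation (lumping) for codon models.

The heuristic: at each alignment position, all codons that are never
observed at the tips are merged into a single "meta-state".  Transition
probabilities into the meta-state are summed; transitions out of it are
averaged with stationary-frequency weights:

    p~_{i,j}   = p_{i,j}                          (i, j not aggregated)
    p~_{i,C}   = sum_{k in C} p_{i,k}
    p~_{C,j}   = (1/pi~_C) sum_{k in C} pi_k p_{k,j}
    p~_{C,C}   = (1/pi~_C) sum_{k,l in C} pi_k p_{k,l}
    pi~_C      = sum_{k in C} pi_k

The aggregated chain is exactly Markov only when the strong-lumpability
condition holds (all merged states have identical transition behaviour),
which GY94-type matrices violate — so the aggregated likelihood is a
heuristic approximation of the full one.  The same lumping applied to a
rate matrix Q additionally resets the diagonal to minus the off-diagonal
row sum so rows still sum to zero.

Strategies: ``none``, ``conserved_only`` (aggregate only invariant sites),
``full`` (meta-state = all unobserved codons), ``amino_acid`` (meta-state =
codons of unobserved amino acids), plus two randomised controls
(``random_shuffled``, ``random_split``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .codon_space import CodonSpace
from .substitution_models import RateMatrix, TransitionMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .likelihood import Alignment

STRATEGIES = (
    "none",
    "conserved_only",
    "full",
    "amino_acid",
    "random_shuffled",
    "random_split",
)


@dataclass(frozen=True)
class ObservedSet:
    """Codon indices observed at one alignment position (codon units)."""

    site_index: int
    codons: frozenset[int]

    def __len__(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class Partition:
    """An ordered partition of the state space into disjoint groups.

    ``aggregated_group`` marks the meta-state group when the partition came
    from an observed-set strategy; ``None`` for the identity partition and
    for the random-split control (which may hold several multi-state
    groups).
    """

    groups: tuple[tuple[int, ...], ...]
    n_states: int
    aggregated_group: int | None = None

    def __post_init__(self) -> None:
        flat = sorted(s for g in self.groups for s in g)
        if flat != list(range(self.n_states)):
            raise ValueError("groups must partition the full state space")

    @property
    def M(self) -> int:
        """Number of states after aggregation."""
        return len(self.groups)

    @property
    def m(self) -> int:
        """Size of the aggregated meta-state set (0 if none)."""
        if self.aggregated_group is None:
            return 0
        return len(self.groups[self.aggregated_group])

    @property
    def is_identity(self) -> bool:
        return self.M == self.n_states

    def labels(self) -> np.ndarray:
        """State -> group-index array of length n_states."""
        lab = np.empty(self.n_states, dtype=np.intp)
        for g, members in enumerate(self.groups):
            lab[list(members)] = g
        return lab

    def membership_matrix(self) -> np.ndarray:
        """n x M one-hot indicator A with A[s, group(s)] = 1."""
        A = np.zeros((self.n_states, self.M))
        A[np.arange(self.n_states), self.labels()] = 1.0
        return A


@dataclass(frozen=True)
class AggregatedChain:
    """Lumped transition matrix with its lumped stationary frequencies."""

    P_tilde: np.ndarray
    pi_tilde: np.ndarray
    partition: Partition


def identity_partition(n_states: int) -> Partition:
    return Partition(
        groups=tuple((i,) for i in range(n_states)),
        n_states=n_states,
        aggregated_group=None,
    )


def _singletons_plus_meta(observed: Sequence[int], n_states: int) -> Partition:
    """Singleton groups for `observed` states, one meta-state for the rest."""
    observed = sorted(observed)
    meta = tuple(s for s in range(n_states) if s not in set(observed))
    if not meta:
        return identity_partition(n_states)
    groups = tuple((s,) for s in observed) + (meta,)
    return Partition(groups=groups, n_states=n_states, aggregated_group=len(observed))


def observed_states(alignment: "Alignment", site: int, space: CodonSpace) -> ObservedSet:
    """Collect the codons observed unambiguously at one codon column.

    Triplets containing gaps or non-ACGT characters contribute nothing, so a
    fully gapped column yields an empty set.
    """
    if not 0 <= site < alignment.n_sites:
        raise IndexError(f"site {site} out of range [0, {alignment.n_sites})")
    codons = set()
    for seq in alignment.sequences:
        codon = seq[3 * site : 3 * site + 3]
        idx = space.index.get(codon)
        if idx is not None:
            codons.add(idx)
    return ObservedSet(site_index=site, codons=frozenset(codons))


def aggregation_scheme(
    obs: ObservedSet,
    strategy: str,
    space: CodonSpace,
    rng_seed: int = 0,
) -> Partition:
    """Build the aggregation partition for one site under a strategy.

    ``random_shuffled`` expects `obs` to be the *donor* site's observed set
    (the caller performs the site permutation, e.g. `site_partitions`); the
    partition is then simply the donor's full-strategy partition.
    ``random_split`` draws a random assignment of all states into the same
    number of groups as the full strategy would produce.
    """
    n = space.n_states
    if strategy == "none":
        return identity_partition(n)
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    observed = sorted(obs.codons)
    if not observed:
        # all-gap column: nothing to anchor the meta-state on
        return identity_partition(n)
    if strategy == "conserved_only":
        if len(observed) == 1:
            return _singletons_plus_meta(observed, n)
        return identity_partition(n)
    if strategy in ("full", "random_shuffled"):
        return _singletons_plus_meta(observed, n)
    if strategy == "amino_acid":
        observed_aas = {space.aa_of[space.codons[s]] for s in observed}
        kept = [i for i, c in enumerate(space.codons) if space.aa_of[c] in observed_aas]
        return _singletons_plus_meta(kept, n)
    # random_split: random assignment of states to M groups, none empty,
    # matching the state count of the full strategy.
    M = min(len(observed) + 1, n)
    rng = np.random.default_rng(rng_seed)
    while True:
        lab = rng.integers(0, M, size=n)
        if len(np.unique(lab)) == M:
            break
    groups = tuple(tuple(np.flatnonzero(lab == g)) for g in range(M))
    return Partition(groups=groups, n_states=n, aggregated_group=None)


def site_partitions(
    alignment: "Alignment",
    strategy: str,
    space: CodonSpace,
    seed: int = 0,
) -> list[Partition]:
    """Per-site partitions for a whole alignment.

    Handles the shuffled control's site permutation: under
    ``random_shuffled`` site *i* receives the full-strategy partition built
    from site ``sigma(i)``'s observed set, with sigma a seeded permutation.
    """
    obs = [observed_states(alignment, s, space) for s in range(alignment.n_sites)]
    if strategy == "random_shuffled":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(alignment.n_sites)
        return [
            aggregation_scheme(obs[perm[s]], "random_shuffled", space)
            for s in range(alignment.n_sites)
        ]
    return [
        aggregation_scheme(o, strategy, space, rng_seed=seed + o.site_index) for o in obs
    ]


def _lump(M_matrix: np.ndarray, pi: np.ndarray, part: Partition) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted lumping of a row-stochastic or rate matrix."""
    A = part.membership_matrix()
    pi_tilde = A.T @ pi
    if np.any(pi_tilde <= 0):
        raise ZeroDivisionError("aggregated group has zero stationary frequency")
    lumped = (A.T @ (pi[:, None] * M_matrix) @ A) / pi_tilde[:, None]
    return lumped, pi_tilde


def aggregate_probability_matrix(
    P: TransitionMatrix | np.ndarray, pi: np.ndarray, part: Partition
) -> AggregatedChain:
    """Lump a transition matrix P under a partition.

    Works for arbitrary partitions (the formulas above are the special case
    of a single aggregated group; singleton groups reduce to the original
    entries).
    """
    P_arr = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    pi = np.asarray(pi, dtype=float)
    P_tilde, pi_tilde = _lump(P_arr, pi, part)
    return AggregatedChain(P_tilde=P_tilde, pi_tilde=pi_tilde, partition=part)


def aggregate_rate_matrix(Q: RateMatrix, pi: np.ndarray, part: Partition) -> RateMatrix:
    """Lump a rate matrix Q; the diagonal is reset so rows sum to zero."""
    Q_tilde, pi_tilde = _lump(Q.Q, np.asarray(pi, dtype=float), part)
    np.fill_diagonal(Q_tilde, 0.0)
    np.fill_diagonal(Q_tilde, -Q_tilde.sum(axis=1))
    return RateMatrix(Q=Q_tilde, pi=pi_tilde)


def is_lumpable(
    P: TransitionMatrix | np.ndarray, part: Partition, tol: float = 1e-10
) -> bool:
    """Strong-lumpability test for a partition.

    True iff, for every group, the summed transition probability into every
    *other* group is identical across the group's member states (within
    ``tol``).  When it holds, the lumped chain is itself Markov and the
    aggregated likelihood is exact.
    """
    P_arr = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    A = part.membership_matrix()
    into_groups = P_arr @ A  # (n, M): row i, summed prob into each group
    for g, members in enumerate(part.groups):
        if len(members) < 2:
            continue
        rows = into_groups[list(members)]
        other = np.delete(rows, g, axis=1)
        if np.any(np.abs(other - other[0]) > tol):
            return False
    return True
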