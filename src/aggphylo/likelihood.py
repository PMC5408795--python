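"""Felsenstein pruning over codon alignments, with optional state aggregation.

Layout conventions
------------------
Trees are stored as flat node arrays; every non-root node owns the branch
above it (length in expected substitutions per codon, plus a foreground
flag for branch-site models).  Alignment columns are compressed into unique
site patterns; under aggregation each pattern carries its own partition of
the 61-codon space, and patterns sharing a partition shape (same number of
retained singleton states m) are pruned together in vectorised batches of
per-pattern lumped matrices.

The exact (non-aggregated) path exponentiates one 61x61 matrix per branch
per rate class and prunes all patterns at once; the aggregated path lumps
those same matrices per pattern before pruning, which is where the heuristic
saves work in a low-level implementation (see `experiments.predicted_speedup`
for the cost model).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .aggregation import (
    ObservedSet,
    Partition,
    aggregate_probability_matrix,
    identity_partition,
    site_partitions,
)
from .codon_space import CodonSpace, build_codon_space
from .substitution_models import (
    BranchSiteParams,
    M0Params,
    build_m0_rate_matrix,
    eigendecompose,
    transition_matrix,
)

_ALLOWED_CHARS = frozenset("ACGTN-")
_FG_MARKER = "@FG@"


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """An in-frame codon alignment: equal-length DNA strings over ACGTN-."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must have equal length")
        length = lengths.pop() if lengths else 0
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        for name, seq in zip(self.names, self.sequences):
            bad = set(seq) - _ALLOWED_CHARS
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence {name!r}")

    @property
    def n_sites(self) -> int:
        """Alignment length in codons."""
        return len(self.sequences[0]) // 3 if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)


def codon_codes(alignment: Alignment, space: CodonSpace) -> np.ndarray:
    """(n_sites, n_taxa) codon-index matrix; -1 marks gap/ambiguous triplets."""
    codes = np.full((alignment.n_sites, alignment.n_taxa), -1, dtype=np.int64)
    for t, seq in enumerate(alignment.sequences):
        for s in range(alignment.n_sites):
            idx = space.index.get(seq[3 * s : 3 * s + 3])
            if idx is not None:
                codes[s, t] = idx
    return codes


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    index: int
    label: str | None
    length: float
    parent: int | None
    children: list[int] = field(default_factory=list)
    foreground: bool = False

    @property
    def is_tip(self) -> bool:
        return not self.children


class Tree:
    """Rooted phylogeny with branch lengths and foreground branch flags.

    Each non-root node owns the branch above it; its ``foreground`` flag
    marks that branch (PAML's ``#1`` tag).  Likelihoods on reversible models
    are invariant to the root position (pulley principle), so reading an
    unrooted Newick with a basal multifurcation is fine.
    """

    def __init__(self, nodes: list[TreeNode], root: int):
        self.nodes = nodes
        self.root = root
        labels = [n.label for n in self.nodes if n.is_tip]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        if any(n.length < 0 for n in self.nodes if n.index != root):
            raise ValueError("branch lengths must be nonnegative")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Tree":
        nodes: list[TreeNode] = []
        index_of: dict[int, int] = {}
        for nd in dtree.preorder_node_iter():
            idx = len(nodes)
            index_of[id(nd)] = idx
            label = nd.taxon.label if nd.taxon is not None else nd.label
            foreground = False
            if label and label.endswith(_FG_MARKER):
                label = label[: -len(_FG_MARKER)] or None
                foreground = True
            parent = index_of[id(nd.parent_node)] if nd.parent_node is not None else None
            nodes.append(
                TreeNode(
                    index=idx,
                    label=label,
                    length=float(nd.edge.length or 0.0),
                    parent=parent,
                    foreground=foreground,
                )
            )
            if parent is not None:
                nodes[parent].children.append(idx)
        return cls(nodes, root=0)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse Newick; PAML-style ``#1`` marks the foreground branch."""
        other_tags = set(re.findall(r"#\s*(\d+)", newick)) - {"1"}
        if other_tags:
            raise ValueError(f"unsupported branch tags: #{sorted(other_tags)}")
        tagged = re.sub(r"\s*#\s*1", _FG_MARKER, newick)
        try:
            dtree = dendropy.Tree.get(
                data=tagged,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as err:
            raise ValueError(f"malformed Newick (duplicate labels or syntax): {err}") from err
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        def fmt(idx: int) -> str:
            node = self.nodes[idx]
            if node.is_tip:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                core += node.label or ""
            if node.foreground:
                core += " #1"
            if idx == self.root:
                return core
            return f"{core}:{node.length:.12g}"

        return fmt(self.root) + ";"

    # -- structure ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def tips(self) -> list[int]:
        return [n.index for n in self.nodes if n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def K(self) -> int:
        """Number of internal nodes."""
        return sum(1 for n in self.nodes if not n.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.tips]

    def postorder(self) -> list[int]:
        order: list[int] = []

        def walk(idx: int) -> None:
            for c in self.nodes[idx].children:
                walk(c)
            order.append(idx)

        walk(self.root)
        return order

    @property
    def edges(self) -> list[int]:
        """Non-root node indices (each identifies the branch above it)."""
        return [n.index for n in self.nodes if n.index != self.root]

    def total_length(self) -> float:
        return sum(self.nodes[e].length for e in self.edges)

    def scale_to(self, target_length: float) -> None:
        """Rescale all branch lengths so they sum to ``target_length``."""
        current = self.total_length()
        if current <= 0:
            raise ValueError("cannot rescale a zero-length tree")
        factor = target_length / current
        for e in self.edges:
            self.nodes[e].length *= factor

    def set_foreground(self, node_index: int) -> None:
        for n in self.nodes:
            n.foreground = False
        if node_index == self.root:
            raise ValueError("the root has no branch to flag")
        self.nodes[node_index].foreground = True

    @property
    def foreground_edges(self) -> list[int]:
        return [e for e in self.edges if self.nodes[e].foreground]


# ---------------------------------------------------------------------------
# Site patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SitePattern:
    """A unique codon column: per-tip codon index (-1 = missing) and weight."""

    tip_codes: tuple[int, ...]
    weight: int
    observed_set: ObservedSet


def site_patterns(alignment: Alignment, space: CodonSpace | None = None) -> list[SitePattern]:
    """Compress alignment columns into unique patterns (first-occurrence order)."""
    if space is None:
        space = build_codon_space()
    codes = codon_codes(alignment, space)
    seen: dict[tuple[int, ...], int] = {}
    patterns: list[SitePattern] = []
    counts: list[int] = []
    first_site: list[int] = []
    for s in range(alignment.n_sites):
        key = tuple(codes[s])
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(patterns)
            patterns.append(key)  # type: ignore[arg-type]
            counts.append(1)
            first_site.append(s)
    out = []
    for key, w, s in zip(patterns, counts, first_site):
        obs = frozenset(c for c in key if c >= 0)
        out.append(
            SitePattern(tip_codes=tuple(key), weight=w, observed_set=ObservedSet(s, obs))
        )
    return out


def tip_vector(pattern: SitePattern, tip: int, part: Partition) -> np.ndarray:
    """Conditional vector of one tip under a partition.

    Observed codon -> indicator of the group holding it (a singleton for
    observation-derived partitions); missing data -> all ones.
    """
    code = pattern.tip_codes[tip]
    if code < 0:
        return np.ones(part.M)
    vec = np.zeros(part.M)
    vec[part.labels()[code]] = 1.0
    return vec


# ---------------------------------------------------------------------------
# Reference per-site pruning
# ---------------------------------------------------------------------------

def prune_site(
    tree: Tree,
    P_per_branch: dict[int, np.ndarray],
    pattern: SitePattern,
    pi_eff: np.ndarray,
    part: Partition | None = None,
) -> float:
    """Single-site Felsenstein pruning; reference implementation.

    ``P_per_branch`` maps each non-root node to its (possibly lumped)
    transition matrix; ``pi_eff`` is the root frequency vector in the same
    (possibly lumped) space.  Per-node scaling guards against underflow.
    """
    pi_eff = np.asarray(pi_eff, dtype=float)
    M = pi_eff.shape[0]
    if part is None:
        part = identity_partition(M)
    tip_pos = {t: k for k, t in enumerate(tree.tips)}
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for idx in tree.postorder():
        node = tree.nodes[idx]
        if node.is_tip:
            vec = tip_vector(pattern, tip_pos[idx], part)
        else:
            vec = np.ones(M)
            for c in node.children:
                P = P_per_branch[c]
                if P.shape != (M, M):
                    raise ValueError(
                        f"matrix for branch {c} has shape {P.shape}, expected {(M, M)}"
                    )
                vec = vec * (P @ partials[c])
            top = vec.max()
            if top > 0:
                vec = vec / top
                log_scale += np.log(top)
        partials[idx] = vec
    lik = float(pi_eff @ partials[tree.root])
    return lik * np.exp(log_scale)


# ---------------------------------------------------------------------------
# Batched pruning engine
# ---------------------------------------------------------------------------

def _is_singletons_plus_meta(part: Partition) -> bool:
    g = part.aggregated_group
    return (
        g is not None
        and g == part.M - 1
        and all(len(grp) == 1 for grp in part.groups[:-1])
    )


@dataclass
class _Batch:
    """Patterns sharing a singleton+meta partition of the same width m."""

    m: int
    rows: np.ndarray          # indices into the engine's global pattern list
    obs: np.ndarray           # (B, m) retained singleton codon indices
    tipL: np.ndarray          # (n_tips, B, m+1) tip conditional vectors


class PruningEngine:
    """Compiled pruning state for one (alignment, tree, strategy) triple.

    All parameter-independent work — pattern compression, per-site
    partitions, tip conditional vectors, batching by partition width —
    happens once here; `loglik` then evaluates the (mixture) likelihood for
    any parameter values from per-branch 61x61 transition matrices.
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: Tree,
        strategy: str = "none",
        seed: int = 0,
        space: CodonSpace | None = None,
    ):
        self.space = space or build_codon_space()
        self.tree = tree
        self.strategy = strategy
        n = self.space.n_states
        tip_order = tree.tips
        labels = tree.tip_labels
        name_to_col = {nm: i for i, nm in enumerate(alignment.names)}
        missing = set(labels) - set(alignment.names)
        if missing:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        codes = codon_codes(alignment, self.space)  # (n_sites, n_taxa)
        # reorder columns to match tree tip order
        col_idx = [name_to_col[lab] for lab in labels]
        codes = codes[:, col_idx]

        if strategy == "none":
            parts = [identity_partition(n)] * alignment.n_sites
        else:
            parts = site_partitions(alignment, strategy, self.space, seed=seed)

        def part_key(p: Partition):
            return "I" if p.is_identity else p.groups

        buckets: dict[tuple, int] = {}
        entries: list[tuple[np.ndarray, Partition]] = []
        weights: list[int] = []
        for s in range(alignment.n_sites):
            key = (tuple(codes[s]), part_key(parts[s]))
            if key in buckets:
                weights[buckets[key]] += 1
            else:
                buckets[key] = len(entries)
                entries.append((codes[s], parts[s]))
                weights.append(1)

        self.weights = np.asarray(weights, dtype=float)
        self.n_patterns = len(entries)
        self.n_tips = len(tip_order)
        self._tip_nodes = tip_order

        full_rows: list[int] = []
        by_m: dict[int, list[int]] = {}
        self._generic: list[tuple[int, np.ndarray, Partition]] = []
        self._entries = entries
        for i, (col, part) in enumerate(entries):
            if part.is_identity:
                full_rows.append(i)
            elif _is_singletons_plus_meta(part):
                by_m.setdefault(part.M - 1, []).append(i)
            else:
                self._generic.append((i, col, part))

        # full (61-state) path
        self._full_rows = np.asarray(full_rows, dtype=np.intp)
        if full_rows:
            cols = np.stack([entries[i][0] for i in full_rows])  # (Bf, n_tips)
            tipL = np.zeros((self.n_tips, len(full_rows), n))
            for t in range(self.n_tips):
                c = cols[:, t]
                amb = c < 0
                tipL[t][amb] = 1.0
                rows = np.flatnonzero(~amb)
                tipL[t][rows, c[rows]] = 1.0
            self._tipL_full = tipL
        else:
            self._tipL_full = None

        # batched singleton+meta path
        self._batches: list[_Batch] = []
        for m, rows in sorted(by_m.items()):
            B = len(rows)
            obs = np.empty((B, m), dtype=np.intp)
            for b, i in enumerate(rows):
                part = entries[i][1]
                obs[b] = [g[0] for g in part.groups[:-1]]
            # position of each codon within the batch partition (meta = m)
            pos = np.full((B, n), m, dtype=np.intp)
            pos[np.arange(B)[:, None], obs] = np.arange(m)[None, :]
            tipL = np.zeros((self.n_tips, B, m + 1))
            for t in range(self.n_tips):
                c = np.array([entries[i][0][t] for i in rows])
                amb = c < 0
                tipL[t][amb] = 1.0
                bidx = np.flatnonzero(~amb)
                tipL[t][bidx, pos[bidx, c[bidx]]] = 1.0
            self._batches.append(
                _Batch(m=m, rows=np.asarray(rows, dtype=np.intp), obs=obs, tipL=tipL)
            )

        # precompute postorder over internal nodes with children lists
        self._postorder_internal = [
            idx for idx in tree.postorder() if not tree.nodes[idx].is_tip
        ]
        self._tip_slot = {t: k for k, t in enumerate(tip_order)}
        # edges inside each node's subtree: the memo key for sharing partial
        # vectors between site classes that agree on all of them
        self._subtree_edges: dict[int, np.ndarray] = {}
        for v in tree.postorder():
            acc: list[int] = []
            for c in tree.nodes[v].children:
                acc.append(c)
                acc.extend(self._subtree_edges[c].tolist())
            self._subtree_edges[v] = np.asarray(sorted(acc), dtype=np.intp)

    # -- pruning paths ------------------------------------------------------

    def _prune_shared(
        self,
        classes: list[int],
        mat_idx: np.ndarray,
        contrib_fn,
        tip_partial_fn,
        root_fn,
    ) -> dict[int, np.ndarray]:
        """Postorder pruning over several site classes with partial sharing.

        Internal-node partials are memoised on the matrix indices of the
        edges inside the node's subtree, so classes that differ only on the
        foreground branch (e.g. 0 vs 2a) recompute only the root path.
        Returns per-class log site likelihood arrays.
        """
        tree = self.tree
        memo: dict[tuple[int, bytes], tuple[np.ndarray, np.ndarray]] = {}

        def prune(v: int, c: int) -> tuple[np.ndarray, np.ndarray]:
            key = (v, mat_idx[c, self._subtree_edges[v]].tobytes())
            hit = memo.get(key)
            if hit is not None:
                return hit
            acc = None
            logacc = None
            for ch in tree.nodes[v].children:
                if tree.nodes[ch].is_tip:
                    Lc = tip_partial_fn(ch)
                else:
                    Lc, la = prune(ch, c)
                    logacc = la if logacc is None else logacc + la
                contrib = contrib_fn(mat_idx[c, ch], Lc)
                acc = contrib if acc is None else acc * contrib
            top = acc.max(axis=-1)
            safe = np.where(top > 0, top, 1.0)
            with np.errstate(divide="ignore"):
                logtop = np.log(top)
            total_log = logtop if logacc is None else logacc + logtop
            result = (acc / safe[..., None], total_log)
            memo[key] = result
            return result

        out = {}
        for c in classes:
            root_L, logacc = prune(tree.root, c)
            with np.errstate(divide="ignore"):
                out[c] = root_fn(root_L) + logacc
        return out

    @staticmethod
    def _lump_batch(Pmats: np.ndarray, obs: np.ndarray, pi: np.ndarray) -> np.ndarray:
        """Lump a stack of 61x61 stochastic matrices for a whole batch.

        Exploits row-stochasticity and stationarity of pi so only the
        observed-by-observed block needs gathering:

            meta column  = 1 - row sums over the block
            meta row     = (pi_obs - pi_obs . block) / pi_meta

        Returns (D, B, m+1, m+1) lumped matrices.
        """
        D = Pmats.shape[0]
        B, m = obs.shape
        pi_obs = pi[obs]                            # (B, m)
        pi_meta = 1.0 - pi_obs.sum(axis=1)          # (B,)
        pi_meta = np.maximum(pi_meta, 1e-300)
        blk = Pmats[:, obs[:, :, None], obs[:, None, :]]      # (D, B, m, m)
        col_meta = np.clip(1.0 - blk.sum(axis=-1), 0.0, 1.0)  # (D, B, m)
        row_num = pi_obs[None] - np.einsum("bi,dbij->dbj", pi_obs, blk)
        row_meta = np.clip(row_num, 0.0, None) / pi_meta[None, :, None]
        corner = np.clip(1.0 - row_meta.sum(axis=-1), 0.0, 1.0)
        Pt = np.empty((D, B, m + 1, m + 1))
        Pt[..., :m, :m] = blk
        Pt[..., :m, m] = col_meta
        Pt[..., m, :m] = row_meta
        Pt[..., m, m] = corner
        return Pt

    def _prune_generic(
        self, idx: int, col: np.ndarray, part: Partition, Pmats: np.ndarray,
        mat_of_node: np.ndarray,
    ) -> float:
        """Slow path for arbitrary partitions (random-split control)."""
        cache: dict[int, np.ndarray] = {}

        def lumped(d: int) -> np.ndarray:
            if d not in cache:
                cache[d] = aggregate_probability_matrix(Pmats[d], self._pi, part).P_tilde
            return cache[d]

        P_per_branch = {e: lumped(mat_of_node[e]) for e in self.tree.edges}
        pit = part.membership_matrix().T @ self._pi
        pattern = SitePattern(
            tip_codes=tuple(col), weight=1, observed_set=ObservedSet(idx, frozenset())
        )
        lik = prune_site(self.tree, P_per_branch, pattern, pit, part)
        return float(np.log(lik)) if lik > 0 else -np.inf

    # -- public API ---------------------------------------------------------

    def loglik(
        self,
        Pmats: np.ndarray,
        mat_idx: np.ndarray,
        log_props: np.ndarray,
        pi: np.ndarray,
    ) -> float:
        """Mixture log-likelihood from per-branch transition matrices.

        Parameters
        ----------
        Pmats:
            (D, 61, 61) stack of distinct transition matrices.
        mat_idx:
            (n_classes, n_nodes) index into ``Pmats`` giving the matrix of
            each branch (child node) under each site class.
        log_props:
            log mixture proportions of the classes.
        pi:
            61-codon stationary frequencies (root frequencies).
        """
        self._pi = np.asarray(pi, dtype=float)
        pi = self._pi
        C = log_props.shape[0]
        per_class = np.full((C, self.n_patterns), -np.inf)
        classes = [c for c in range(C) if np.isfinite(log_props[c])]
        if self._full_rows.size:
            res = self._prune_shared(
                classes,
                mat_idx,
                contrib_fn=lambda d, L: L @ Pmats[d].T,
                tip_partial_fn=lambda ch: self._tipL_full[self._tip_slot[ch]],
                root_fn=lambda L: np.log(L @ pi),
            )
            for c in classes:
                per_class[c, self._full_rows] = res[c]
        for batch in self._batches:
            Pt = self._lump_batch(Pmats, batch.obs, pi)
            pi_obs = pi[batch.obs]
            pit = np.concatenate([pi_obs, (1.0 - pi_obs.sum(1))[:, None]], axis=1)
            res = self._prune_shared(
                classes,
                mat_idx,
                contrib_fn=lambda d, L, Pt=Pt: np.einsum("bij,bj->bi", Pt[d], L),
                tip_partial_fn=lambda ch, b=batch: b.tipL[self._tip_slot[ch]],
                root_fn=lambda L, pit=pit: np.log((L * pit).sum(axis=-1)),
            )
            for c in classes:
                per_class[c, batch.rows] = res[c]
        for idx, col, part in self._generic:
            for c in classes:
                per_class[c, idx] = self._prune_generic(idx, col, part, Pmats, mat_idx[c])
        # combine classes in log space
        shifted = per_class + log_props[:, None]
        top = shifted.max(axis=0)
        top_safe = np.where(np.isfinite(top), top, 0.0)
        with np.errstate(divide="ignore"):
            site_loglik = top_safe + np.log(
                np.exp(shifted - top_safe[None, :]).sum(axis=0)
            )
        return float(self.weights @ site_loglik)


# ---------------------------------------------------------------------------
# Model-level likelihoods
# ---------------------------------------------------------------------------

def _edge_matrix_stack(
    tree: Tree, omega_of_class_edge: dict[tuple[int, int], float], kappa: float,
    pi: np.ndarray, space: CodonSpace, n_classes: int,
    rate_of_omega: dict[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the distinct P(t) stack and the (class, node) -> matrix index map.

    ``rate_of_omega`` holds per-class relative rates under a shared model
    scale (branch-site); each class then sees an effective branch length
    ``t * rate``.
    """
    # group the distinct (omega, edge) cells by omega so each eigensystem is
    # exponentiated for all its branch lengths in one batched product
    edges_of_omega: dict[float, list[int]] = {}
    for (_, e), omega in omega_of_class_edge.items():
        edges = edges_of_omega.setdefault(omega, [])
        if e not in edges:
            edges.append(e)
    mats: list[np.ndarray] = []
    distinct: dict[tuple[float, int], int] = {}
    for omega, edges in edges_of_omega.items():
        rm = build_m0_rate_matrix(M0Params(omega=omega, kappa=kappa, pi=pi), space)
        es = eigendecompose(rm)
        rate = 1.0 if rate_of_omega is None else rate_of_omega[omega]
        ts = np.array([tree.nodes[e].length * rate for e in edges])
        explam = np.exp(np.outer(ts, es.Lambda))  # (n_e, 61)
        P_all = (es.U[None, :, :] * explam[:, None, :]) @ es.U_inv
        np.clip(P_all, 0.0, 1.0, out=P_all)
        P_all /= P_all.sum(axis=2, keepdims=True)
        for k, e in enumerate(edges):
            distinct[(omega, e)] = len(mats)
            mats.append(P_all[k])
    mat_idx = np.zeros((n_classes, tree.n_nodes), dtype=np.intp)
    for (c, e), omega in omega_of_class_edge.items():
        mat_idx[c, e] = distinct[(omega, e)]
    return np.stack(mats), mat_idx


def m0_system(
    tree: Tree, params: M0Params, space: CodonSpace
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    omega_map = {(0, e): params.omega for e in tree.edges}
    Pmats, mat_idx = _edge_matrix_stack(tree, omega_map, params.kappa, params.pi, space, 1)
    return Pmats, mat_idx, np.array([0.0]), params.pi


def branch_site_system(
    tree: Tree, params: BranchSiteParams, space: CodonSpace
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    from .substitution_models import SITE_CLASSES, branch_site_rate_multipliers

    omega_map = {}
    for c, site_class in enumerate(SITE_CLASSES):
        for e in tree.edges:
            btype = "foreground" if tree.nodes[e].foreground else "background"
            omega_map[(c, e)] = params.class_omega(site_class, btype)
    Pmats, mat_idx = _edge_matrix_stack(
        tree, omega_map, params.kappa, params.pi, space, len(SITE_CLASSES),
        rate_of_omega=branch_site_rate_multipliers(params, space),
    )
    with np.errstate(divide="ignore"):
        log_props = np.log(params.proportions)
    return Pmats, mat_idx, log_props, params.pi


def m0_loglikelihood(
    alignment: Alignment,
    tree: Tree,
    params: M0Params,
    strategy: str = "none",
    seed: int = 0,
    engine: PruningEngine | None = None,
) -> float:
    """Log-likelihood of an alignment under M0 (exact or aggregated)."""
    space = engine.space if engine is not None else build_codon_space()
    if engine is None:
        engine = PruningEngine(alignment, tree, strategy=strategy, seed=seed, space=space)
    return engine.loglik(*m0_system(tree, params, space))


def branch_site_loglikelihood(
    alignment: Alignment,
    tree: Tree,
    params: BranchSiteParams,
    strategy: str = "none",
    seed: int = 0,
    engine: PruningEngine | None = None,
) -> float:
    """Log-likelihood under the branch-site mixture (exact or aggregated)."""
    space = engine.space if engine is not None else build_codon_space()
    if engine is None:
        engine = PruningEngine(alignment, tree, strategy=strategy, seed=seed, space=space)
    return engine.loglik(*branch_site_system(tree, params, space))
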