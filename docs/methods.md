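# Methods

## Models

### The codon substitution process

All computations run on the 61 sense codons of the standard genetic code
(stops excluded), in fixed lexicographic order.  The substitution process is
the Goldman–Yang (GY94) continuous-time Markov chain: for codons *i* ≠ *j*
differing at exactly one nucleotide position,

    q_ij = pi_j                    synonymous transversion
    q_ij = kappa pi_j              synonymous transition
    q_ij = omega pi_j              nonsynonymous transversion
    q_ij = omega kappa pi_j        nonsynonymous transition

and q_ij = 0 for codons differing at two or more positions.  kappa > 0 is
the transition/transversion rate ratio, omega ≥ 0 the nonsynonymous/
synonymous rate ratio (dN/dS), and pi the codon equilibrium frequencies
(equal, empirical counts with add-one smoothing, or F3x4).  The M0 model
applies a single omega to all sites and branches.  Q is rescaled so that
−Σᵢ πᵢ q_ii = 1, making branch lengths expected substitutions per codon.

### The branch-site model

The branch-site model (model A) is a four-class site mixture.  With one
designated *foreground* branch and proportions p0, p1, p2a =
(1−p0−p1)·p0/(p0+p1), p2b = (1−p0−p1)·p1/(p0+p1):

| class | background omega | foreground omega | proportion |
|-------|-----------------|------------------|------------|
| 0     | omega0 ∈ [0,1]  | omega0           | p0         |
| 1     | 1               | 1                | p1         |
| 2a    | omega0          | omega2 ≥ 1       | p2a        |
| 2b    | 1               | omega2           | p2b        |

The positive-selection test compares the alternative (omega2 free) against
the null (omega2 = 1) with 2·(lnL_alt − lnL_null) referred to chi²(1).
Because the null places omega2 on the boundary, the chi²(1) reference is
conservative; we keep it as it is the convention of the inference software
this package parallels (the 50:50 boundary mixture would be the
alternative choice).

**Scaling of the class matrices.**  All class matrices share a single scale
factor: branch lengths are expected substitutions per codon averaged over
the site classes on background branches, f = (p0+p2a)·mu(omega0) +
(p1+p2b)·mu(1), where mu(w) is the mean rate of the unnormalised GY94
generator with omega = w.  A class with omega value w then evolves at
relative rate mu(w)/f, so positively selected sites genuinely accelerate on
the foreground branch.  We deliberately do *not* rescale each class matrix
to mean rate one: doing so erases the rate signature of omega2, leaving
only the substitution-composition signal on the foreground branch, which we
measured (on exact 2-taxon pattern distributions) to be nearly reproducible
by a null mixture — about 2·10⁻⁴ nats per site at omega2 = 10 — i.e. the
LRT would have essentially no power.  The shared-scale convention matches
codeml/evolver behaviour.

## State aggregation

At each alignment position, codons never observed among the tip sequences
are merged ("lumped") into one meta-state.  Given a transition matrix P and
stationary frequencies pi, a merged set C gets

    p~_{i,C} = Σ_{k∈C} p_{i,k}
    p~_{C,j} = (Σ_{k∈C} pi_k p_{k,j}) / pi~_C,   pi~_C = Σ_{k∈C} pi_k

with unmerged entries unchanged; applied to a rate matrix Q the diagonal is
afterwards reset to minus the off-diagonal row sum.  The lumped chain is
Markov only under strong lumpability (all merged states transitioning
identically), which GY94 matrices violate — aggregated likelihoods are a
heuristic approximation, exact in the lumpable and fully-observed limits
(both are tested).

Strategies: `conserved_only` (only invariant sites, M = 2),
`full` (meta-state = all unobserved codons, M = observed + 1),
`amino_acid` (meta-state = codons of unobserved amino acids), and two
randomised controls: `random_shuffled` (full-strategy meta-states permuted
across sites with a seeded permutation) and `random_split` (a random
assignment of all 61 states into the same number of groups as `full`;
uniformity over set partitions is not attempted).  Aggregation is applied
to P after exponentiation, per site; Q-level lumping is provided but not
used by default inference.

Numerical conventions: pi in the lumping formulas is the model equilibrium
vector (shared across branch-site classes), not empirical column
frequencies; pi~ is renormalised defensively; all-gap columns receive the
identity partition with all-ones tip vectors; the root frequency vector of
an aggregated site is the lumped pi~.

## Likelihood evaluation

Felsenstein pruning with per-node scaling (log-scaler accumulation) guards
against underflow on long trees.  Alignment columns are compressed to
unique site patterns.  The engine exponentiates one 61×61 matrix per branch
per distinct omega (via the symmetric transform diag(√pi)·Q·diag(1/√pi),
whose real spectrum makes `eigh` applicable, with negative P(t) entries
clamped and rows renormalised), then:

- patterns whose partition is the identity are pruned together fully
  vectorised at 61 states;
- aggregated patterns are batched by retained-state count m and pruned with
  per-pattern lumped matrices, built from only the observed-by-observed
  block of P (row-stochasticity and stationarity give the meta-state row
  and column in closed form);
- the random-split control takes a per-pattern generic path.

Internal-node partial vectors are memoised on the matrix indices of the
subtree below them, so branch-site classes that differ only on the
foreground branch (0 vs 2a, 1 vs 2b) share most of the pruning work.
Likelihood is computed on the tree as rooted in the input; for these
reversible models the root placement is immaterial (pulley principle).

## Inference

Bounded L-BFGS-B on transformed parameters (log omega/kappa, logit omega0,
1+exp for omega2, softmax over (p0, p1, rest)), finite-difference
gradients, convergence tolerance 1e-10 on the scaled objective.  Bounds:
omega ∈ [1e-4, 50], kappa ∈ [1e-2, 100], omega2 ∈ [1, 999], branch lengths
∈ [1e-8, 50] when optimised.  Branch-site fits are multi-started from
three fixed points (omega0, omega2, p0, p1) = (0.1, 2, 0.7, 0.2),
(0.5, 5, 0.4, 0.4), (0.9, 1.5, 0.2, 0.6) — mixture surfaces are
multi-modal — using a short exploratory run from each start and a full
polish from the best endpoint.  A `max_evals` cap reproduces
fixed-budget optimisation.  Non-convergence is flagged, the best point
returned.

## Synthetic data

The simulator draws the root codon from pi and evolves each site down the
tree with the class-appropriate P(t) per branch (matrix-exponential
sampling — equivalent in distribution to event-level simulation).  Trees
are birth–death (dendropy's sampler) conditioned on the tip count, branch
lengths rescaled to a target total length; two-tip trees are a cherry by
construction.

Replicate designs for the branch-site studies draw from stand-in
distributions chosen to span biologically realistic ranges: kappa ~
LogUniform(1, 6), omega0 ~ Uniform(0.05, 0.95), omega2 ~ 1 + Exp(mean 2),
p0+p1 ~ Uniform(0.6, 0.99) split uniformly, alignment length ~
Uniform{100..600} codons, tips ~ Uniform{6..24}, tree length ~
LogUniform(0.5, 15); the foreground branch is uniform over branches; even
seeds give null (omega2 = 1) replicates so contiguous seed ranges are
balanced.  All are overridable per run.

The extended branch-site generator replaces omega0 and omega2 by five
equal-probability discretised categories (Beta for omega0; 1 + Gamma for
omega2; category value = median of its probability slice) and multiplies
each site's branch lengths by a Gamma(shape, mean 1) rate — data that
violate the inference model's homogeneity assumptions the way real genes
do.

What the generator does *not* emulate: indels and alignment error,
non-stationary or non-reversible evolution, codon-frequency variation
across the tree, site-to-site dependence, and topology/branch-length
estimation error (topologies are taken as known).  Passing tests therefore
demonstrate correctness of the machinery and behaviour of the heuristic
under the model, not robustness to real-data pathologies beyond the
extended-model misspecifications listed above.

## Experiments and the cost model

Wall-clock speedups are hardware- and implementation-dependent, so the
experiments validate the *analytic* cost model instead: with unit costs
t_eigen, t_exp, t_prun, t_agg,

    T_full = t_eigen + K·t_exp + N·K·61·t_prun
    T_aggr = t_eigen + K·t_exp + N·K·t_agg + N·K·M·t_prun

and the predicted speedup is their ratio (by default with the t_exp terms
dropped, as eigendecomposition and pruning dominate).  Monotone
relationships — speedup grows with alignment length N and falls with the
mean aggregated state count M, which itself grows with tree length — are
asserted on this model and on simulated observed-codon counts.

The accuracy/consistency studies rerun the replicate design above at
reduced scale (the package defaults to tens to low hundreds of replicates
with alignment lengths 100–250 and 6–12 taxa for its own test suite and
acceptance script; full-size runs are a CLI flag away).  Reported outputs:
Pearson correlations between full-mode and aggregated-mode estimates
(omega2 over alternative replicates only), LRT decision cross-tables for
null and alternative replicates, TP/TN/FP/FN against the simulated truth,
the decision agreement fraction, and ROC/AUC over the LRT statistic.

## Known limitations

- Aggregated likelihoods are biased for extremely long trees (saturation
  regime); the heuristic is intended for the short-to-moderate tree lengths
  typical of real alignments.
- The branch-site LRT at these reduced data sizes has modest power for
  omega2 close to 1; type-I calibration is conservative by construction.
- Only the standard genetic code is supported; partial codon ambiguities
  are treated as fully missing.
- The Python implementation's own run times do not mirror the cost model's
  constants; the model describes low-level implementations where pruning
  dominates.
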