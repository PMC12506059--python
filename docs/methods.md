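# Methods

This note documents the statistical procedures implemented in
`famnet`, the choices made where a design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Cross-sectional network (module `ggm`)

**Model.** Symptom subscale scores for a family triad are modelled as
multivariate Gaussian; the network is the partial-correlation matrix,
whose zeros encode conditional independence.  Summed Likert subscales
are treated as continuous throughout (the usual psychometric
convention; ordinal estimators are out of scope).

**Estimator.** Each node is z-standardized and regressed on all others
with an L1 penalty (the Gaussian special case of a mixed graphical
model).  The per-node penalty is chosen by 10-fold cross-validation by
default (fold assignment seeded, so fits are reproducible from
`(data, config, seed)`); extended BIC selection
(`EBIC = n log(RSS/n) + k log n + 2γ k log d`, γ = 0.25) over a
50-point log-spaced path is available as `penalty_selection="ebic"`
and is used by the bootstrap- and permutation-heavy stages, where its
speed matters (the path is solved by a numba-compiled coordinate
descent on the Gram matrix).

Cross-validated lasso alone is not support-consistent — it retains
many tiny spurious coefficients — so, following the default behaviour
of the mgm estimator this module mirrors, nodewise coefficients below
the Loh–Wainwright bound `τ_j = √(d_j log p / n)` (`d_j` = selected
neighbourhood size) are set to zero (`threshold="lw"`, the default;
`"none"` disables it).

**AND rule and aggregation.** An edge is retained only if both directed
regressions select it.  The edge weight is the *mean* of the two
standardized coefficients, which coincides with the partial correlation
up to the (small) difference between arithmetic and geometric means of
the two precision diagonals.  Pairs selected with conflicting signs are
zeroed with a logged warning; they indicate estimation noise, not a
meaningful edge.

**Subgroups.** Networks for child sex, child age bands (<10, 10–12,
13–15) and household income are fitted with identical settings per
group.  Income tertiles are rank-based: the ⌊n/3⌋ lowest- and
highest-income families are retained and the middle discarded.

## Bridge centrality (module `bridge`)

Bridge edges are nonzero edges whose endpoints carry different
family-member labels.  Bridge strength of node v is
`Σ |w(v,u)|` over nodes u of other members.  Bridge betweenness uses
the standard association-network distance transform `1/|w|` and
Brandes-style fractional path counting: for every unordered pair (s, t)
with *different* member labels, each interior node accumulates the
fraction of shortest s–t paths passing through it.  Pairs within one
member never contribute, even when another member's node lies between
them; endpoints never accumulate; disconnected pairs contribute
nothing; ties are split fractionally, never arbitrarily.  Raw
(unnormalized) counts are reported.

## Stability (module `stability`)

Case dropping samples *without replacement* at sizes
`round((1 − p) n)` over the grid p = 0.05, …, 0.75, refits with the
full pipeline, and correlates each subsample statistic vector (edge
weights, strength, or bridge strength) with the full-sample vector.
Undefined correlations (constant vectors, failed refits — one retry,
then recorded missing) are stored as NaN and excluded from quantiles.
The CS coefficient is the largest p whose empirical 5th percentile of
correlations exceeds 0.70 *and does so at every smaller p* (prefix
rule — the definition presumes a monotone decay, so a window that
fails is treated as terminal even if a later one passes).  "Edge
structure" stability is operationalized as the correlation of
vectorized edge weights.  Default `n_boot = 1000`; tests and the
analysis drivers run 100–200 per drop proportion.

## Network comparison test (module `nct`)

Observed statistic per tested edge: `E = |w₁ − w₂|`; global statistics:
the maximum edge difference M and the global-strength difference S.
Null distribution: rows are pooled and randomly reassigned to groups of
the original sizes; *both networks are refitted per permutation with
the identical estimation pipeline, penalty selection included* — the
null must mirror the full procedure, not reuse frozen penalties.
P-values use the add-one rule `p = (1 + #{E* ≥ E}) / (1 + n_perm)`,
which cannot be zero at finite n_perm and keeps the test valid (if
slightly conservative).  Tested edges default to the union of bridge
edges nonzero in either group; Holm's step-down adjustment is applied
across them.

## Panel graphical VAR (module `panel_gvar`)

**Moment structure.**  With stationary S0 solving
`S0 = B S0 Bᵀ + K_within⁻¹`, the stacked nodes-by-waves observation has
within-family covariance blocks `cov(y_s, y_t) = S0 (Bᵀ)^{t−s}` plus
`K_between⁻¹` in every block, and mean `μ` repeated per wave.  Waves
are treated as equally spaced measurement occasions; unequal spacing in
real cohorts is a documented limitation (the estimation window is
configurable).

**Likelihood.** FIML: each family contributes the Gaussian log-density
of its observed entries under the corresponding sub-mean and
sub-covariance.  Families are grouped by missingness pattern purely for
speed; the result is identical for any grouping (tested against
per-family brute-force marginals at 1e−10).  Families with fewer than
two observed waves are excluded upstream (`filter_longitudinal`), and
the likelihood refuses them.  Within an observed wave the long-to-wide
pivot applies a complete-case rule per member's item set.

**Parameterization and optimization.** Free parameters are μ, the
unmasked entries of B, and the diagonals plus unmasked off-diagonals of
the two precision matrices (symmetric entries tied).  Precision
matrices are parameterized *directly by their elements* rather than by
Cholesky factors: pruning fixes precision off-diagonals to exactly
zero, which a square-root parameterization cannot express.  Positive
definiteness and stationarity (spectral radius < 0.999) are maintained
by a large likelihood penalty that the L-BFGS line search backs away
from; with data generated from a stationary process the optimum is
interior and the barrier is inactive at convergence.  The gradient is
analytic — the missing-pattern contributions `∂ℓ/∂Σ` are chained
through the block structure and the Lyapunov map by an adjoint
equation `Λ = Bᵀ Λ B + P` — and verified against finite differences in
the test suite.  Point estimates are plain FIML; standard errors are
observed-information (central-difference Hessian of the analytic
gradient).  A sandwich ("robust") correction is deliberately not the
default: which robustness target (non-normality, clustering) it should
address is analysis-specific, so the plain observed-information SEs are
the documented baseline.

**Model search.** The saturated model frees all edges.  Pruning
recursively fixes to zero every off-diagonal with Wald p ≥ 0.05 and
refits until all survivors are significant (means, diagonals and
variances are never pruned).  The step-up search scores each fixed
edge by a score-test modification index `g²/H` (gradient and curvature
of the likelihood in the fixed parameter at the restricted optimum,
with |g| as fallback when the curvature is unusable), frees the
strongest candidate, refits, and keeps the change only if the
information criterion (BIC by default) improves — so accepted steps
can never worsen BIC.  Fit indices use `T = 2(ℓ_sat − ℓ_m)`,
`RMSEA = √(max(0, T − df)/(df·N))` (defined as 0 when df = 0) and
CFI against the independence baseline (all off-diagonals of B and both
precisions zero, autoregressions and variances retained) — the
baseline choice is an assumption, stated here because the convention
varies.

## Synthetic-data generators (module `synthetic_data`)

Ground truth is parameterized by precision/coefficient matrices so that
positive definiteness and stationarity are enforceable; the
partial-correlation views are derived.  The cross-sectional triad truth
uses a unit-diagonal precision (entries are then exactly the implied
partial correlations): within-member edges 0.3, mother–father bridges
0.15 per dimension, mother–child bridges 0.12 (emotional symptoms and
loss of confidence to child internalising/externalising), and no
independent father–child edge — the qualitative structure reported for
real family cohorts.  The panel truth places positive autoregressions
(0.3) on all 13 item nodes, innovations equicorrelated at 0.3 within a
member, random-intercept variance 0.4 (stable family traits carry
roughly a third of total variance), and whatever cross-member lag-1
paths the caller plants (the drivers use the mother-overwhelmed →
child-worry → child-nervous → mother-overwhelmed loop).

Missingness is missing-completely-at-random at the wave level — real
cohort attrition is neither known nor random, so passing FIML tests
here demonstrates correctness of the likelihood under MCAR, not
robustness to informative dropout.  Likert discretization uses
equal-mass standard-normal thresholds.  Subgroup covariates are
assigned independently of symptom levels unless group-specific truths
are supplied, which is what makes the subgroup NCT a type-I-error
check.  The generators emulate neither survey weights, household-grid
linkage, sibling structure, nor selection into complete triads.

## Problem sizes and numerical conventions

Tests and the acceptance script run at sizes chosen to make each
property sharply decidable on one CPU: n = 50,000 for exact-support
recovery of the 9-node network; 100 bootstrap resamples per drop
proportion; 200 replications × 200 permutations for NCT calibration
(25 replications at n = 5000/group for power); 100,000–200,000
simulated families for Monte-Carlo moment checks; and 10–25 seeded
pipeline runs at 2000 families × 4 waves × 6 nodes for loop recovery.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`); bootstrap and
permutation index sets are pre-generated, so results are identical for
any worker count.  Optimizer tolerances: L-BFGS-B with `ftol = 1e−11`,
`gtol = 1e−5`, convergence accepted when the per-family gradient norm
falls below 1e−3.

## Known limitations

Gaussian treatment of Likert items assumes equal spacing; coarse items
will bias partial correlations toward zero.  The AND-rule mean
aggregation is one of several defensible conventions.  The step-up
search is greedy and can stop at a local BIC optimum.  RMSEA/CFI are
computed from the FIML likelihood ratio without small-sample or
non-normality corrections.  The panel model assumes one set of
dynamics shared by all families (random intercepts only, no random
slopes) and lag-1 effects on an equally spaced wave grid.
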