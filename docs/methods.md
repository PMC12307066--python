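# Methods

This note documents the statistical model, the numerical choices and the
synthetic-data design behind `coocmix`, and what the test suite does and
does not demonstrate.

## Co-occurrence metric

The spatial association of a species pair is the log odds ratio θ of
Fisher's non-central hypergeometric distribution (NHD) for the
co-occurrence count, conditional on both occupancies and the site total.
Three properties drive the package design:

1. a non-overlapping pair is the most probable outcome for rare species
   over a wide range of θ, so absence of co-occurrence is weak evidence;
2. a pair observed at a support bound (no co-occurrences, or the maximum
   possible) has no finite maximum-likelihood estimate — `theta_mle`
   returns an explicit boundary flag (`neg_infinite`/`pos_infinite`), and
   a support with a single point (a count forced by the margins) returns
   `undefined`. Flags, never floating infinities, propagate downstream;
3. information about θ grows with occupancy, so assemblage-level inference
   must pool pairs.

### Numerics

All pmf arithmetic is in log space with log-gamma binomial coefficients
and log-sum-exp; the support is finite, so the normalizer P0(θ) is exact,
not truncated. This is overflow-free for |θ| ≤ 50 and site totals in the
tens of thousands. `theta_mle` solves the monotone mean equation
E[N_AB | θ] = N_AB by bracketed root-finding on θ ∈ [−50, 50] (tolerance
1e−8) after boundary screening; monotonicity of the conditional mean
guarantees the bracket. The pmf mode breaks exact ties toward the smaller
count; values within 1e−9 on the log scale count as tied, because
log-gamma rounding can perturb an exact tie by an ulp. For batches of
pairs, `SupportTable` stores the support in a flat segmented layout and
evaluates all pointwise log-likelihoods in a single vectorised pass.

## Data preparation

* **Habitat**: the nine register disturbance categories collapse to
  intact (`none`) versus altered (anything else).
* **Guild overlap**: high = identical {primary, secondary} guild multisets
  (order ignored); medium = some but not all guilds shared, or any
  omnivore (omnivory overrides); low = disjoint. Low-overlap pairs act as
  the control group.
* **Diet pairing**: the unordered pair of full guild strings, e.g.
  `frugivore|nectarivore`.
* **Phylogenetic distance**: node counts on the tip-to-tip path. The
  default convention counts internal nodes strictly between the tips
  (sister tips = 1); an edge-count convention is available. The two differ
  by a constant +1, which the subsequent standardization absorbs, so the
  choice only relabels the scale. Polytomies are honoured as given.
  Distances are logged, centred and scaled to mean 0 / variance 1
  (population sd), binned into five equal-width intervals over the
  standardized range (left-closed; last bin closed), and every pair in a
  bin is assigned the bin's mean standardized distance. Standardization is
  computed over the pooled pair records of both habitats so that a single
  slope is interpretable across habitats.
* **Species pools**: species lacking guild or tree information are
  excluded with a manifest before pairing; the restricted-pool option
  keeps only species occurring in both habitat types, separating changed
  spatial relationships from compositional turnover.

## Hierarchical model and sampler

θ_pair = Xβ + u_set (+ v_dietpair), NHD likelihood, treatment contrasts
with reference levels low overlap and intact habitat, so the intercept is
the low-overlap/intact expectation at average (standardized distance 0)
relatedness. Random effects are zero-mean normal; the set-level standard
deviation is constant or grouped by guild overlap or habitat. Grouping is
resolved at the set level and validated: the grouping variable must be
constant within every set, which holds whenever it (or a finer variable —
diet pairing determines guild overlap) is among the set-defining
variables. Pairs with single-point supports stay in the likelihood
(contributing exactly zero) and are counted in diagnostics.

Priors (the sources of the model family are silent on them; these are the
usual weakly-informative defaults of that software family, and are
configurable): β ~ Normal(0, 5²), σ ~ half-Student-t(3, 0, 2.5).

Inference is an adaptive Metropolis-within-Gibbs sampler, chosen because
the model's structure makes three cheap, well-mixing move types available:

* **Set intercepts**: all u_s are updated simultaneously by componentwise
  random-walk proposals — sets are conditionally independent given β and
  σ, so per-set accept/reject vectorises over the whole assemblage.
* **Compensated location moves**: any fixed-effect column that is constant
  within every set (the intercept always; others whenever their variable
  is among the set-defining variables) admits a move that shifts β_j and
  counter-shifts every u_s so the linear predictor — hence the likelihood
  — is exactly unchanged; acceptance depends only on the priors. These
  moves decorrelate β from the random effects.
* **Group scale moves**: for each variance group, u_g → u_g·e^δ jointly
  with log σ_g → log σ_g + δ. The Normal(u|0,σ) terms cancel against the
  proposal Jacobian, so σ is informed directly by the likelihood. Without
  this interweaving-style move the centred parameterization leaves σ
  coupled to slowly-moving u's and R̂ for the σ's stalls above 2; with it,
  split-R̂ values settle near 1.01–1.08 at the chain lengths used here.
* Fixed effects additionally get a joint random-walk update with a
  covariance adapted during warm-up, and σ a conditional log-scale
  random-walk. All proposal scales adapt by Robbins–Monro during warm-up
  only (diminishing adaptation), targeting acceptance 0.3 (joint) / 0.44
  (componentwise).

Chains are deterministic given a seed (per-chain child seeds from a seed
sequence). The default geometry — 4 chains × 3000 steps, 1000 warm-up,
thinning 2, i.e. 4000 retained draws — matches the full-scale analysis
configuration; tests and examples use reduced geometries (noted inline)
chosen so a desk-scale run finishes in seconds per fit. Convergence is
monitored by split-R̂ (optionally rank-normalized) with a warning
threshold of 1.05.

## Model comparison and selection

ELPD is estimated by PSIS-LOO: importance ratios are the reciprocal
pointwise likelihoods, the largest ~20% smoothed by a generalized-Pareto
fit (`arviz.psislw`); Pareto k > 0.7 is flagged. A degenerate posterior
(identical draws) falls back to the plain pointwise log-likelihood with a
warning. Model pairs are summarized by ΔE, its standard error s_ΔE from
the pointwise differences, and z_ΔE = ΔE/s_ΔE — an informal evidence
score, not a test: every species enters many pairs, so the pointwise
values are not independent. A 0/0 ratio (identical models) is reported as
0 with a degeneracy flag.

Structure selection is two-step — random structure first under the full
fixed structure, then fixed structure under the chosen random structure.
Within each step the winner maximizes ELPD, moderated by the
**one-standard-error parsimony rule**: among candidates whose ELPD is
within one pairwise standard error of the best, the simplest (fewest
parameters) wins. Plain maximization is available (`parsimony_se=0`) but
is not the default, because for nested candidates the expected ELPD
penalty for one superfluous parameter is O(1) and comparable to its own
standard error — under plain maximization a null term survives selection
roughly half the time regardless of sample size. Single-term importance
in a final model is reported by z_ΔE of one-term-poorer refits, removing
interactions before their main effects.

## Randomization nulls

The curveball algorithm trades occupied columns between random row pairs,
preserving all row and column sums exactly; a mixing curve (fraction of
occupied cells displaced versus trade count) lets users justify trade
counts. The documented full-scale setting is 1e8 trades per matrix; the
desk-scale default is 50 trades per occupied cell, which sits on the
plateau of the mixing curve for the matrix sizes used in the tests. Null
distributions refit the chosen model to each randomized matrix with
covariates rebuilt against the unchanged phylogeny and guild tables —
the randomization deliberately ignores both, so observed estimates
falling outside the null envelope indicate that those structures shape
co-occurrence. The default randomizes the full matrix; a per-habitat
option randomizes each habitat's sub-matrix separately. Replicate seeds
derive from a master seed via a counter; failed replicate fits are
recorded and excluded.

## Synthetic data

Two tiers, deliberately separate:

* **Pair level** — exact: covariates are sampled i.i.d. per pair
  (log-series-like occupancies, p = 0.93, truncated to the 50-site worked
  scale, reflecting that rare taxa dominate real assemblages; guild pairs
  drawn from a five-guild pool with 30% secondary guilds and 5%
  omnivores; right-skewed integer node distances standardized and binned
  through the production code path), sets receive u ~ Normal(0, σ_group),
  and counts are exact NHD draws at θ = Xβ + u. Generative defaults are
  the assemblage-scale conditions: 5000 pairs, slope −0.10, intercept
  0.41, medium-overlap contrast +0.34, σ = 0.60/0.53/0.87 for
  low/medium/high overlap.
* **Matrix level** — heuristic: a Yule tree, Brownian niche traits mixed
  with independent noise (`phylo_signal`), optionally phylogenetically
  clustered guilds, and logistic site-by-niche occupancy calibrated per
  species to log-series occupancy targets. A site-by-species matrix
  cannot carry arbitrary prescribed pairwise θ for all pairs at once (the
  margins over-constrain it), so this tier claims only directional
  structure and feeds end-to-end pipeline tests; exact truth lives at the
  pair level.

What passing tests show — and don't: pair-level recovery demonstrates
that the estimator and sampler are correct **when the model is true**;
matrix-level checks demonstrate directional behaviour (phylogenetic
signal induces a negative distance-slope; structure-free matrices sit
inside curveball null envelopes). Neither demonstrates robustness to
misspecification in real assemblages (spatial autocorrelation, sampling
effort gradients, non-normal set effects), which is out of scope here.

## Problem sizes and tolerances in the test suite

Exhaustive kernel verification runs over every margin combination with
≤ 60 total sites against naive direct summation (1e−10). The estimation
oracle compares 1000 random tables against a six-stage zoomed grid search
(1e−6). Recovery uses 20 replicates of 5000 pairs with 2 chains × 1200
steps; selection uses 10 replicates at 5000 pairs; null envelopes use 100
curveball refits of a 40-species, 30-site structure-free assemblage with
single short chains. These sizes were chosen so that each statistical
check retains a clear signal while a full suite run stays in the tens of
minutes on one core.

## Known limitations

* The sampler is random-walk based; posteriors with thousands of sets mix
  well thanks to the compensated/scale moves, but models with strongly
  correlated fixed effects beyond the compensable set would benefit from
  a gradient-based sampler (the architecture accepts one).
* PSIS-LOO leaves out one pair, not one species; with singleton sets the
  left-out pair carries its own random effect and Pareto k values above
  0.7 are common. The exact-LOO agreement test covers the small-instance
  regime; at assemblage scale the ELPD is best read comparatively, as the
  selection procedure does.
* θ's insensitivity to the number of sites is treated as an empirical
  property (examined in simulation), not an enforced invariant.
* Node-count distances ignore branch lengths by construction; trees with
  very uneven taxon sampling will compress parts of the distance scale.
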