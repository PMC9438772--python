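# Methods

## The problem

Multi-template PCR — the amplification step behind 16S/ITS amplicon
sequencing — copies each template with its own per-cycle efficiency.
Sequencing then reports *relative* abundances, so efficiency differences do
not simply rescale counts: through the constant-sum constraint they bend
every template's trajectory, including templates whose absolute kinetics are
perfectly exponential.  `pcrbias` models this jointly compositional/kinetic
process, estimates per-template efficiencies from a replicated multi-cycle
calibration experiment, reconstructs the community profile at any cycle
(including the approximated unbiased profile at cycle 0) and tests sequence
covariates as drivers of efficiency differences.

## Kinetic model

For one template with initial amount z, original-template efficiency
θ ∈ (0, 1] and product efficiency λ ∈ (0, 1], the product count obeys the
recurrence c(t) = θz + (λ+1)c(t−1) with c(1) = θz, whose closed form is

    c(t) = (θz/λ) ((λ+1)^t − 1).

θ and z appear only as the product θz and are never separately identifiable.
For t beyond a few cycles the −1 is negligible and c(t) ≈ (θz/λ)(λ+1)^t,
with relative error exactly (λ+1)^(−t).  The model assumes constant
efficiencies within the log-linear phase: no substrate competition, plateau
or cycle-dependent rates.

## Composition space

Observed counts are compositional, and each library carries an unknown
scale factor A.  We work in isometric log-ratio (ILR) coordinates defined by
a rooted binary tree over the templates: each internal node contributes one
"balance" contrasting its left against its right subclade, with the
orthonormal, zero-row-sum contrast matrix Ψ built from the tree's sign
matrix by the usual √(n₋n₊/(n₋+n₊)) scaling.  Zero row sums make the ILR
invariant to A exactly.  Under the approximate kinetics the balances are
*linear in cycle number*:

    b(t) = t·log(λ+1)·Ψᵀ − log(λ)·Ψᵀ + a,     a = ilr(θz).

Orientation conventions (first Newick child = left = −1; internal-node rows
in preorder) are arbitrary but fixed for reproducibility; results are
invariant to them.  Multifurcating trees are rejected rather than silently
resolved, because an arbitrary resolution would change the basis.

## Preprocessing

The pipeline mirrors standard amplicon practice: optional rarefaction to a
common depth (sampling without replacement, i.e. multivariate
hypergeometric, seeded), a prevalence filter keeping templates observed
*strictly more than* `min_count` (default 10) times in at least
`min_fraction` (default 50%) of libraries, and Bayesian-multiplicative zero
replacement under a symmetric Dirichlet prior.  The default prior strength
is 1/n per component (total strength 1); it is configurable because the
method family leaves it open.  Only zeros are imputed; non-zero entries are
multiplicatively shrunk so library totals are conserved.

## Hierarchical model and sampler

Balances of replicate j at cycle t are modelled as

    b^tj ~ Normal(b(t), diag(σ²)),  λᵢ ~ Beta(4, 1),
    aᵢ ~ Normal(0, 2),  σᵢ ~ HalfNormal(1),

with Σ diagonal by construction and the Normal(0, 2) read as standard
deviation 2.  Two structural facts shape the inference:

* only the contrast log(λ+1)Ψᵀ enters the slope, so the common level of
  log(λ+1) across templates is informed by the prior alone — contrasts are
  what the data identify (hence recovery is scored on correlations);
* for fixed (λ, σ) the model is linear-Gaussian in the per-balance
  intercept c = a − log(λ)Ψᵀ.

We exploit the second fact by integrating c out analytically (its prior,
induced by a's prior, is Gaussian) and sampling only (logit λ, log σ) with
an affine-invariant ensemble sampler (`emcee`) using differential-evolution
and snooker moves.  For every retained draw, c — and hence a — is drawn
exactly from its Gaussian conditional.  The collapsed density involves only
the sufficient statistics of the per-balance regression of b on t, so one
evaluation costs O(n) regardless of the number of libraries, and it has
been verified against numerical quadrature to 1e-12.

Sampler settings: `tune` burn-in moves are discarded; the retained window
spans `thin × ceil(draws/walkers)` further moves (defaults 500 / 64 × 16 =
1024, i.e. roughly fifteen integrated autocorrelation times at the default
design), thinned so each of `chains` independent ensembles contributes
`draws` retained samples.  Each ensemble is one chain for rank-normalised
R-hat and bulk ESS (arviz); each retained step is flattened walker-major so
consecutive draws come from different walkers.  Walkers start from a
per-balance ordinary-least-squares fit of b on t, overdispersed along the
prior-identified common level.  A mean acceptance fraction below 0.15 is
logged as a warning, the ensemble analogue of divergent transitions.  The
study-scale configuration (5000 tuning / 20 000 draws / 4 chains) is
available by passing those numbers; defaults are desk-scale.

Degenerate designs fail loudly: a single distinct cycle raises an
identifiability error (the slope, hence λ, is unconstrained).

## Reconstruction and bias summaries

Given posterior draws (λ, a), the community at cycle t ≥ 1 is the closure
of ẑᵢ/λᵢ((λᵢ+1)^t − 1) with ẑ = ilr⁻¹(a); at t = 0 the closed form
vanishes, so by convention the approximated initial (efficiency-biased)
profile closure(ẑ) is reported.  Posterior-predictive compositions sample
b ~ Normal(b(t), diag(σ²)) per draw and invert the ILR; the predictive mean
uses the exact reconstruction, which differs from the fitted linear balance
model only by the geometrically vanishing (λ+1)^(−t) term.  Log-ratio
change summaries (median, IQR across draws of log x(t₂)/x(t₁) per template)
quantify amplification bias between any two cycles; both the cycle-0 and
cycle-1 baselines are supported since either can serve as "initial".

## Synthetic data

The generator reproduces the calibration design: 5 consecutive cycles
(22–26) × 12 replicates at multinomial depth 9988 (the study's rarefaction
depth).  Random binary trees are built by uniform pairwise joining; λ is
drawn from Beta(4, 1), a from Normal(0, 2), σ from HalfNormal(0.05) — the
tight replicate noise of a single-master-mix run, distinct from the
weakly-informative inference prior on σ.  For each library the kinetic line
is evaluated at its cycle, diagonal Gaussian noise is added in balance
space (matching the inference model), the result is mapped back to the
simplex, multiplied by a LogNormal per-library scale factor and sequenced
multinomially.  Because the multinomial probabilities are the closure of
the scaled expectation, the scale factor provably never reaches the counts
— the generator encodes the same invariance the ILR exploits.  An optional
"efficiency" noise mode jitters λ per replicate instead, for studying the
model under its own misspecification.  Synthetic template sequences have
controlled GC content, and their paired "secondary-structure energy"
covariate is a recorded linear function of GC and log λ plus noise
(defaults: no GC term, so GC is a null covariate; a positive log λ term, so
energy carries a real signal), serving as positive/negative controls for
the covariate analyses.

What the generator does *not* emulate: sequencing error, chimeras, taxonomy
mis-assignment, overdispersion beyond multinomial, cycle-dependent
efficiencies and template competition.  Passing recovery tests therefore
show the estimator works when its own assumptions (plus counting noise)
hold — not that real libraries satisfy those assumptions.

## Calibration experiments (what the acceptance script measures)

`recovery_trial` runs the full loop — simulate at the study design,
prevalence-filter (as the real pipeline would; templates too rare to clear
the filter carry almost no balance information, which is why the filter
exists), shear the tree to the survivors, zero-replace, fit — and scores
the posterior against the generating truth restricted to the surviving
subcomposition (compositional subsetting preserves the kinetic model
exactly).  Over 20 repeats at the default design we observe Pearson
correlations between true and posterior-mean log(λ+1) above 0.9 in every
repeat, and 95% credible-interval coverage for a near nominal.  Coverage is
assessed with repeats as the unit of replication (intervals within a repeat
are correlated), using the binomial band 0.95 ± 2√(0.95·0.05/20).  Under
the exactly specified model (very deep sequencing) coverage is consistent
with 0.95; at depth 9988 the multinomial counting noise absent from the
diagonal-Gaussian balance model produces a few points of undercoverage —
a real, documented property of the method, shared by any fit of this model
to counted data.

## Covariate analyses

Efficiency point estimates are posterior means of log λ (posterior medians
available).  The Mantel test correlates upper-triangle entries of the
pairwise Levenshtein distance matrix (via `edlib`) with |Δ log λ| (squared
differences optional), with p-values from joint row/column permutations
using the (1 + exceedances)/(1 + permutations) convention.  The regression
log(λ) ~ GC + E uses Huber M-estimation (tuning 1.345, IRLS to 1e-8;
Tukey bisquare selectable) via statsmodels; energies are used exactly as
supplied (kcal/mol, negative = more stable), with no transforms.

## Numerical choices and limitations

* All logarithms are natural; λ is validated against (0, 1], never clamped.
* Proposals with |logit λ| or |log σ| > 30 are rejected outright (no
  posterior mass, avoids overflow).
* Closure tolerance 1e-12; ILR round-trip verified to 1e-10; contrast
  orthonormality to 1e-10.
* Default problem sizes (10–20 templates, 20 recovery repeats, 1000 Mantel
  null simulations with 999 permutations, 200 regression repeats) were
  chosen as the smallest designs that make the calibration experiments
  statistically meaningful on a single desk-class CPU.
* The observation model is diagonal Gaussian in balance space: it ignores
  counting noise (mild undercoverage at finite depth, see above) and
  heavier-tailed replicate variation; a multivariate-t observation model is
  a natural extension point but is not implemented.
* Leave-one-out prior tuning is out of scope; priors are fixed defaults,
  overridable via `PriorConfig`.
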