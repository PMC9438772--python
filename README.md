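# pcrbias

Compositional modelling and Bayesian calibration of multi-template PCR
amplification bias in amplicon sequencing.

## The problem

Amplicon sequencing (16S, ITS, ...) amplifies every template in a community
with its own per-cycle efficiency.  Because sequencing reports only
*relative* abundances, heterogeneous efficiencies do not merely rescale
counts — through the constant-sum constraint they distort every template's
apparent trajectory, non-linearly, even when each template's absolute
kinetics are perfectly exponential.  `pcrbias` is for microbiome
researchers who want to quantify, and correct for, this bias using a
calibration experiment: the same community amplified for several
consecutive cycle numbers in replicate.

## The model

For template i with initial amount `z_i`, template efficiency `θ_i` and
product efficiency `λ_i ∈ (0, 1]`, the product count at cycle t is

    c_i(t) = (θ_i z_i / λ_i) ((λ_i + 1)^t − 1)  ≈  (θ_i z_i / λ_i) (λ_i + 1)^t,

the approximation error being exactly `(λ_i + 1)^{−t}`.  Working in
isometric log-ratio (ILR) coordinates defined by a rooted binary tree over
the templates — whose orthonormal, zero-row-sum contrast matrix `Ψ`
cancels each library's unknown scale factor — the balances are linear in
cycle number:

    b(t) = t · log(λ+1) Ψᵀ − log(λ) Ψᵀ + a,     a = ilr(θz).

Replicate balances are modelled as `b^tj ~ N(b(t), diag(σ²))` with priors
`λ_i ~ Beta(4, 1)`, `a_i ~ N(0, 2)`, `σ_i ~ HalfNormal(1)`, sampled by a
collapsed ensemble MCMC (the per-balance intercept is integrated out
analytically; see `docs/methods.md`).  From the posterior the package
reconstructs the community at any cycle — including the approximated
unbiased profile at cycle 0 — and tests sequence covariates (GC content,
secondary-structure free energy, pairwise edit distance) as drivers of
efficiency differences.

## Worked example

```python
import numpy as np
import pcrbias as pb

# a synthetic calibration run at the standard design:
# 5 cycles (22-26) x 12 replicates, multinomial depth 9988
truth = pb.make_truth(n=10, seed=7)
exp = pb.simulate_experiment(truth)

# the study pipeline: prevalence filter, zero replacement, ILR, fit
exp_f = pb.prevalence_filter(exp)                     # keeps 8 of 10 here
basis = pb.ContrastBasis.from_tree(
    truth.basis.tree.copy().shear(list(exp_f.template_ids))
)
obs = pb.build_observations(exp_f, basis, counts=pb.zero_replace(exp_f))
post = pb.fit(obs, basis, seed=11)

lam_hat = post.lambda_draws.mean(axis=0)
print(pb.bias_summary(post, basis, 22, 26, seed=0).round(3))
```

Posterior-mean efficiencies track the generating truth (first rows):

```
template  lam_true  lam_hat
T003      0.971     0.940
T008      0.797     0.753
T009      0.916     0.886
T004      0.744     0.687
```

with Pearson correlation 0.974 between true and estimated `log(λ+1)` and
clean convergence (max R-hat 1.004, min bulk ESS 1637).  The bias summary
gives each template's posterior log-ratio change between cycles 22 and 26
(median and IQR) — the template with the highest efficiency (`T003`,
λ ≈ 0.97) holds its share (median ≈ 0.00) while slower templates shrink,
e.g. `T007` (λ ≈ 0.76) loses a factor `exp(0.71) ≈ 2` over just four
cycles:

```
template_id  median_log_ratio    q25    q75
       T003             0.003 -0.026  0.031
       T007            -0.709 -0.755 -0.659
```

The same workflow is available from the shell:

```sh
pcrbias simulate --n 10 --seed 7 --outdir run
pcrbias preprocess --counts run/counts.tsv --metadata run/metadata.tsv --outdir prep
pcrbias fit --counts run/counts.tsv --metadata run/metadata.tsv \
    --tree run/tree.nwk --seed 11 --outdir fit
pcrbias associate --posterior-summary fit/posterior_summary.tsv \
    --fasta run/sequences.fasta --energy run/energies.tsv --seed 3 --outdir assoc
```

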