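# Methods

`divmat` analyses the multivariate phenotypic divergence of experimentally
evolved lineages from a common ancestor.  Its statistical core is the
divergence (**D**) matrix — the covariance matrix of lineage trait means —
together with three questions asked of it: how many independent dimensions
of divergence it supports (effective rank), whether its structure differs
between experimental treatments (matrix similarity), and whether a
lineage's total multivariate divergence predicts its fitness gain
(adaptation).

## The mixed model and its restricted likelihood

The observation model for the p = 4 traits (BM, CFU, DPL, SFB; CFU, DPL
and SFB on the natural-log scale) of replicate *j* in lineage *k* of
bottleneck treatment *l* is

    y_jkl = mu_l + u_k + e_jkl,

with fixed treatment means `mu_l` (one free p-vector per treatment),
lineage effects `u_k ~ N(0, D)` and residuals `e ~ N(0, R)` with `R`
unstructured.  A replicate random effect that covaries across traits is
**not identifiable** from this design — the three replicate colonies per
lineage need not be the same physical colonies across traits — so it is
absorbed into `R`.  This convention makes the covariance parameter counts
of the rank ladder come out at p(p+1)/2 = 10 residual parameters plus the
factor-analytic k(2p−k+1)/2, i.e. 20, 19, 17, 14, 10 for k = 4…0.

Fitting is by restricted maximum likelihood (REML).  Rather than
assembling the full N·r·p covariance, the likelihood is factored through
an orthogonal within-lineage transform: lineage means carry covariance
`D + R/r` (plus the fixed effects), and the r−1 within-lineage contrasts
per lineage carry covariance `R`.  The factorization handles unequal
replicate counts per lineage (each lineage contributes its own
`D + R/r_k`).  A brute-force dense evaluator of the same restricted
likelihood (`dense_minus2ll`) is retained and tested against the factored
path on tiny instances over grids of parameter values.

Numerical choices:

- **Parameterization.**  Unstructured matrices via their Cholesky factor
  (free entries, diagonal sign-fixed internally); factor-analytic rank-k
  structures as `D = Λ Λᵀ` with a lower-trapezoid p×k loading matrix
  (zeros above the diagonal of the leading k×k block for identifiability).
  Both keep every iterate positive semi-definite by construction.
- **Optimization.**  L-BFGS-B with numerical gradients, multi-start
  (default 5 seeded starts: a method-of-moments start — between/within
  decomposition of the balanced design — plus seeded perturbations).
  `estimate_rank` additionally warm-starts each FA(k) fit from the
  truncated FA(k+1) solution and refits a higher rank from a padded
  lower-rank solution if the ladder ever turns non-monotone; in practice
  this keeps the −2LL column monotone to well below 1e-6.
- **Degenerate iterates** (residual Cholesky diagonal below 1e-10, or a
  non-PD scale matrix) are rejected with a large objective value rather
  than an exception, so the optimizer routes around them.

### Rank tests

`estimate_rank` fits FA(k) for k = p down to 0 and tests each rank
against the one below by the likelihood-ratio chi-square with df equal to
the parameter-count difference.  The selected rank is the largest k whose
k vs k−1 test is significant at the configured alpha (default 0.05),
scanning downward from p.  The naive chi-square reference is used by
default — these tests sit on the boundary of the parameter space, and the
naive reference is the convention this analysis follows — with the
50:50 mixture correction deliberately left out of the default path.

### Treatment mean test

`treatment_mean_test` is the joint Wald F of the p-dimensional contrast
between treatment means, using the GLS mean estimates and their
covariance from the fitted model; numerator df = p(groups−1), denominator
df by the residual method (total scalar observations minus fixed-effect
rank).  The design's published counterpart reports numerator df 1, which
cannot be reconstructed from the described model; the joint test is
reported instead and this divergence is intentional.

### Pooled vs separate D

`separate_vs_pooled_D` compares one pooled unstructured lineage
covariance against treatment-specific ones (both with a shared
unstructured residual), df = (groups−1)·p(p+1)/2 = 10 for two groups.
The separate fit is warm-started from the pooled solution.

## The Flury (CPC) hierarchy

Treatment-specific D matrices are computed from the unstandardized
lineage means and compared through the nested hypothesis chain equality ⊃
proportionality ⊃ CPC ⊃ partial CPC(q) ⊃ unrelated.  Each model's fit
statistic against the saturated model is
`chi2 = Σ_i m_i ln(det Σ̂_i / det S_i)` with group weight `m_i = n_i − 1`
(the sample-covariance df, matching the convention of the classic CPC
program).  Step chi-squares are obtained by differencing adjacent models'
statistics — this guarantees the telescoping AIC identity
`AIC(model) = chi2_vs_unrelated + 2(T − cum_df)`, `T = (k−1)p(p+1)/2` —
rather than by refitting pairwise likelihoods.  Model choice is by
minimum AIC with ties broken toward the more constrained model.

The common basis comes from the FG algorithm: pairwise Jacobi-style plane
rotations, with each pair's rotation angle found by a coarse grid over
one period of the criterion followed by bounded 1-D refinement.  The grid
step makes the inner problem global and handles tied-eigenvalue pairs
(flat criterion) without special-casing.  Columns are ordered by pooled
variance, each column's largest-magnitude entry made positive.  Partial
CPC(q) shares the q highest-pooled-variance axes and refits the
orthogonal complement freely per group; the basis itself is taken from
the full-CPC solution (the chain remains nested because the shared axis
sets are).

Expected selection behaviour worth knowing: under exact matrix equality,
AIC picks "equality" with probability ≈ 0.76 asymptotically (independent
chi-square increments with df 1, 3, 1, 2, 3 against penalty 2·df), and
less at 30 lineage means per group; this is a property of AIC model
building, not of the implementation.  Power to recognise genuinely
unrelated matrices is modest at 30 means per group and near-certain by
100 per group — the recovery tests therefore run the unrelated-truth case
at 100 lineages per group.

## Divergence geometry and adaptation

Eigenanalysis of D uses the canonical sign convention (largest-magnitude
loading of each eigenvector positive), descending eigenvalues, and
proportions λ_a/Σλ.  Mahalanobis distances from the ancestor use the
D matrix re-estimated with the ancestral mean included (n = 61 rows in
the emulated design); distance is invariant to any common invertible
affine recoding of traits, so raw-scale means are used.  A singular
metric raises by default; the Moore–Penrose pseudo-inverse (relative
eigenvalue cutoff 1e-10) is opt-in, to avoid silent distance deflation.
The ancestor's own record carries distance 0 and ln-distance −inf; a zero
distance for an evolved lineage is an error.

Adaptation is the lineage's mean fitness (MGR) minus the ancestor's.
The adaptation analysis reports Pearson r (p from the t transform of r)
pooled and per treatment, a type-II OLS ANCOVA of adaptation on
ln-distance × treatment, and optionally the OLS regression of adaptation
on treatment plus the four traits.  With one mean per lineage, the
"linear mixed model" version of that regression collapses to OLS, which
is what is implemented.

## The synthetic-data generator

`simulate_experiment` emulates the end-point statistical structure the
analysis assumes — it does **not** simulate the evolutionary process
(mutation supply, clonal interference, fixation).  Defaults are the
emulated design: 2 treatments × 30 lineages × 3 replicates plus a
triplicate ancestor; lineage effects drawn from a full-rank true D
(default: the published pooled divergence matrix, variances ≈ 0.9–2.3 on
the analysis scale); residual covariance 0.25·I (the within-lineage
covariance magnitude is not reported anywhere, so this default is an
arbitrary but plausible choice, documented as such); zero treatment
shift, matching the null treatment effect the design exhibited.
Traits are generated directly on the analysis (post-ln) scale so the
Gaussian mixed model is exact; `raw_scale=True` exponentiates CFU/DPL/SFB
to exercise the transform step.

Fitness: `adaptation_i = α + β ln(d_i^true + 1e-6) + N(0, σ_f)` per
lineage, with the true distance computed in the true-D metric
(pseudo-inverse when the truth is singular).  Replicate MGR values equal
the lineage value — σ_f already represents noise in the lineage mean.
Defaults α = 0.5, β = 0.05 (a 5% fitness gain per e-fold of distance, in
MGR units with an ancestor baseline of 5.0); σ_f = 0.0591 was fixed once
by `calibrate_fitness_noise`, which solves
`r = βs·ρ / sqrt(β²s² + σ_f²)` for σ_f using Monte-Carlo estimates of
the ln-true-distance spread s and the measurement attenuation ρ, so that
the pipeline-recovered distance–adaptation correlation averages the
target 0.262 at n = 60.

Randomness: one root seed feeds independent child streams (lineage
effects, residuals, fitness, basis generation), so toggling the fitness
model never perturbs the trait draws, and identical configs give
byte-identical tables.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: non-Gaussian lineage effects (real
beneficial-mutation effects are few and discrete per lineage),
trait-dependent measurement error, outliers, missing cells, and any
correlation between the number of fixed mutations and the direction of
divergence.

## Test problem sizes

Monte-Carlo suites use sizes chosen to make their statistical assertions
sharp while keeping the default test run quick: rank recovery 100 seeds
at the default design size, null calibration of the matrix-equality test
200 seeds, CPC recovery 100 seeds (unrelated truth at 100 lineages per
group, see above), fitness-link recovery 500 seeds, type-I calibration of
the treatment mean test 100 seeds, and law-of-large-numbers checks of the
generator 200 seeds with element-wise 4·SE tolerances.

## Known limitations

- The REML engine is specific to this nested, (possibly unbalanced)
  two-level design; it is not a general mixed-model engine (no crossed
  random effects, no covariates beyond treatment).
- Partial-CPC fits condition on the full-CPC basis rather than
  re-maximizing the basis per partial model; with well-separated pooled
  eigenvalues the difference is negligible, and the chain stays nested.
- Boundary effects make the naive chi-square rank tests conservative for
  excluding dimensions; this mirrors the convention adopted here.
- No outlier handling or imputation of missing cells, by design.
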