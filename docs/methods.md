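# Methods

## Model

Each stool (or other community) sample `n` is summarized as a vector of read
counts `y_n` over `K` taxa, with per-sample depth `T_n = sum_k y_nk`, plus a
vector `x_n` of `M` binary host properties (disease status, gender, ...).
The model is a finite mixture of multinomials — a unigram mixture — in which
a latent class `z_n` captures enterotype-like interindividual structure while
the host properties act through a single effect matrix shared by all classes:

```
z_n | pi        ~ Categorical(pi)
y_n | z_n, x_n  ~ Multinomial(T_n, p_n),   p_n = softmax(gamma_{z_n} + x_n B)
pi | alpha      ~ Dirichlet(alpha)
beta_m          ~ Normal_K(0, sigma^2 I)       (rows of B, M x K)
gamma_l         ~ Normal_K(0, tau^2 I)         (class baselines, L x K)
```

Because `B` enters additively on the logit scale and identically in every
class, a covariate shifts the log-abundance of each taxon by the same amount
regardless of which community type the sample belongs to.  This is the point
of the model: differential abundance associated with a host property is
estimated after adjusting for community-type structure, which an unadjusted
per-taxon test conflates with the effect of interest.

The latent classes are marginalized analytically, so the observed-data
likelihood is `prod_n sum_l pi_l Multinomial(y_n | softmax(gamma_l + x_n B))`,
evaluated in log space with log-sum-exp.  `p'_l = softmax(gamma_l)` gives the
taxon occurrence probabilities characterizing class `l`.

## Inference

**MAP.** The free parameters are the mixing weights (through a zero-anchored
softmax, `L - 1` entries), the `L x K` baselines, the `M x K` effects, and
optionally `log sigma` and `log tau`.  `alpha` is a fixed hyperparameter
(default all ones, a noninformative choice): the mixing weights themselves are
optimized on the simplex rather than integrated out, which keeps the objective
smooth and the free-parameter count explicit.  The posterior mode is found by
L-BFGS with a hand-derived analytic gradient.  Mixture posteriors are
multimodal, so the optimizer runs from 5 starts: one seeded by k-means on log
relative abundances (pseudo-count 0.5) — baselines from cluster-wise empirical
log-frequencies (centered, to sit well under the Gaussian prior), weights from
cluster proportions, effects at zero — plus jittered copies (baseline noise
SD 0.1).  The best mode is kept.  Convergence is declared when the gradient
infinity-norm is below `1e-5` relative to the magnitude of the log posterior;
a fit that misses this is flagged, never raised.

**Laplace approximation.** At the mode the posterior is approximated by
`N(theta_hat, H^{-1})` with `H` the Hessian of the *negative* log posterior
(stored in that convention so the covariance is its inverse directly).  `H` is
computed by central differences of the analytic gradient (step
`1e-5 (1 + |theta_j|)`); no autodifferentiation library is required, and the
tests cross-check this route against second differences of the objective.
Eigenvalues below `1e-8` times the largest are floored at that threshold
before inversion (with a logged warning): the softmax link leaves
near-flat directions — adding a constant to every entry of a baseline row, or
to a whole row of `B`, does not change the likelihood — that only the Gaussian
priors curve.  Credible intervals are `theta_hat_j ± z_{(1+level)/2}
sqrt(cov_jj)` (default level 0.95); for the occurrence probabilities the
baseline interval endpoints are mapped through the softmax coordinate-wise,
the default in preference to sampling the Laplace normal.

A practical consequence of the flat directions: the likelihood identifies `B`
only up to a common per-covariate shift, and the prior pins the reported
representative near zero mean.  Point estimates of individual coefficients
therefore carry a shared offset of order `|mean_k B_true|` (small when `K` is
large), the per-coefficient intervals inherit the prior-limited width of the
shift direction, and coverage is conservative — which is exactly what the
recovery study shows.

**Classification.** Sample `n` is assigned to the class maximizing the
posterior class probability `pi_l p(y_n | gamma_l, B, x_n) / sum_l' ...`,
computed in log space; ties break toward the smallest index for determinism.

## Model comparison and cluster number

**Evidence.** The log marginal likelihood is approximated at the mode by
`log p(Y | theta_hat, X) + log phi(theta_hat) + (D/2) log 2pi -
(1/2) log |H(theta_hat)|`, with `D` the free-parameter count.  The multinomial
combinatorial constant is included in reported values; it cancels between
models fitted to the same table.  The covariate model M1 is compared against
M0 (all effects pinned at zero, `D` reduced by `M x K`); the larger evidence
wins.  On a Gaussian toy the approximation is exact; on a mildly non-Gaussian
two-parameter toy it is within 1% of quadrature (tested).

**Cluster number.** Candidate class counts `L >= 2` are scored by the
Calinski-Harabasz index `CH_L = (BC_L/(L-1)) / (WC_L/(N-L))` over a pairwise
divergence matrix between the samples' normalized abundance profiles, where
`BC`/`WC` sum the divergence values over between-/within-cluster pairs (each
unordered pair once) and the divergence value itself plays the role of the
squared distance.  The divergence is, deliberately, the symmetrized
Kullback-Leibler form `(1/2)[sum a log(a/b) + sum b log(b/a)]` evaluated after
replacing zeros with a `1e-6` pseudo-count and renormalizing — the form used
in the enterotyping literature this package follows; the bounded textbook
Jensen-Shannon divergence is available behind `variant="jensen_shannon"`.
Labels at each candidate `L` come from the covariate-free mixture fit by
default (selection stays internal to the model); k-medoids on the divergence
matrix — the classical enterotype workflow — is available behind
`method="kmedoids"`.  A degenerate candidate with zero within-cluster
dispersion has infinite CH; it is recorded as the largest finite float plus an
explicit flag.  Note that a strong covariate effect is itself a real axis of
compositional variation and can legitimately raise CH at larger `L`; the
selection is a heuristic over marginal composition, not a likelihood-based
test.

## Synthetic data and the recovery study

The generator draws from the model itself: `B` and the `gamma_l` i.i.d.
standard normal (unless fixed matrices are supplied), `x ~ Bernoulli(0.5)`,
`z ~ Categorical(pi)`, `y ~ Multinomial(depth, softmax(gamma_z + x B))`.
Reference design: 100 samples, 100 taxa, 3 classes with equal weights, depth
2000, one covariate.  Truth is drawn **once** per study and held fixed; each
replicate redraws `x`, `z`, `y` and is refitted from its own seeded stream,
so the whole study is bit-reproducible from a single seed.

Per coefficient of `B`, over `R` replicates: coverage probability (fraction of
replicates whose 95% interval contains the truth), bias `mean(Bhat) - B`,
standard error (SD of `Bhat`, ddof = 1) and RMSE `sqrt(mean((Bhat - B)^2))` —
these satisfy `RMSE^2 = bias^2 + SE^2 (R-1)/R` exactly, which the tests assert
on the recorded draws.  Classification accuracy is scored after aligning
estimated components to the truth by minimum total squared distance between
baseline rows (exhaustive for up to 6 classes, Hungarian assignment beyond);
`B` needs no alignment since it is shared across classes.  Replicates whose
fit fails the convergence check are excluded and counted; more than 20%
failures aborts the study.  The default replicate count is 100 — a desk-scale
choice that keeps the full study at a few minutes on one core while leaving
the per-coefficient coverage estimates with binomial SE ~0.02; larger counts
are a parameter away.

What the generator does *not* emulate: overdispersion relative to the
multinomial (real microbiome counts are typically Dirichlet-multinomial-like
or zero-inflated), uneven sequencing depth, taxonomic correlation structure,
and continuous or correlated covariates.  Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own assumptions,
not robustness to their violation.

## Companion analyses

Cluster-vs-attribute independence uses the Pearson chi-squared test without
continuity correction (`df = (R-1)(C-1)`); a zero marginal is an error.  The
per-taxon baseline is the two-sided Wilcoxon rank-sum test on relative
abundances (midranks with the normal approximation under ties; exact for
small tie-free groups), with Benjamini-Hochberg FDR adjustment across taxa by
default and Bonferroni behind a flag.  A taxon constant across all samples is
reported with p = 1 and a flag.

## Numerical choices and limitations

- Log arguments floored at `1e-300`; responsibilities renormalized after
  exponentiation; all mixture sums via log-sum-exp.
- The multinomial constant is excluded from the optimization objective (it is
  parameter-free) and added back to all reported log-likelihood, posterior and
  evidence values.
- Samples are rows everywhere; taxa-in-rows input files are transposed at read
  time behind an explicit flag.  Relative-abundance inputs are converted to
  pseudo-counts by a multiplier (conventionally 10,000) and half-up rounding.
- `sigma = tau = 1` fixed by default (matching the standard-normal generator
  and a unit-scale prior belief); estimating them on the log scale under the
  flat prior is available behind `estimate_scales`, but a flat prior on a
  scale can drift on degenerate data, so fixed scales are the default for the
  recovery study.
- Evidence values are Laplace approximations; they inherit the quality of the
  Gaussian approximation at the mode and the eigenvalue flooring of near-flat
  directions.  Comparisons between models of very different dimension on tiny
  datasets should be read with that in mind.
- The number of parameters grows as `(L + M) K`; hundreds of taxa and several
  covariates are comfortable, but the dense Hessian (central differences +
  eigendecomposition) is the bottleneck beyond a few thousand free parameters.
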