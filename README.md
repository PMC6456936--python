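# enigma-mixture

Microbiome samples cluster into recurrent community types ("enterotypes")
characterized by signature taxa.  That structure confounds association
testing: a per-taxon two-group test cannot tell whether an abundance shift
reflects the host property under study (e.g. disease status) or merely a
different mix of community types between the groups.  This package fits a
unigram mixture model that estimates both at once — latent community classes
and covariate effects shared across them — so that disease associations are
read off *after* adjusting for community type.  It is aimed at researchers
with a taxa-by-sample count table (any taxonomic level) and a table of binary
host properties.

## Model

For sample `n` with counts `y_n` over `K` taxa, depth `T_n`, and binary host
properties `x_n` (length `M`):

```
z_n ~ Categorical(pi)                       latent community class, L classes
y_n ~ Multinomial(T_n, softmax(gamma_{z_n} + x_n B))
pi ~ Dirichlet(alpha);  beta_m ~ N_K(0, sigma^2 I);  gamma_l ~ N_K(0, tau^2 I)
```

The class baselines `gamma_l` carry the enterotype-like structure; the
`M x K` matrix `B` carries covariate effects on the log-abundance scale,
identical in every class.  Inference is MAP (L-BFGS, multi-start) with a
Laplace approximation at the mode for credible intervals, posterior class
probabilities for sample classification, a Laplace log marginal likelihood
for comparing the covariate model (M1) against the null (M0, `B = 0`), and
Calinski-Harabasz selection of the number of classes over a symmetrized-KL
divergence matrix.  A simulation harness replicates the
generate-fit-score loop and reports per-coefficient coverage, bias, SE, RMSE
and classification accuracy.  See `docs/methods.md` for details.

## Worked example

Simulate a 3-class dataset from the model and refit it:

```python
import numpy as np
from enigma import (SimulationConfig, generate_parameters, generate_dataset,
                    fit_map, FitConfig, align_labels, compare_models)

config = SimulationConfig(n_samples=100, n_taxa=100, n_classes=3,
                          total_count=2000, n_covariates=1, seed=1)
truth = generate_parameters(config, seed=1)
Y, X, z_true = generate_dataset(truth, config, seed=2)

fit = fit_map(Y, X, L=3, config=FitConfig(seed=0))
perm = align_labels(fit.params.gamma, truth.gamma)
print("converged:", fit.converged)
print("mixing weights:", np.round(fit.params.pi, 3))
print("classification accuracy:", np.mean(perm[fit.assignments] == z_true))

comp = compare_models(Y, X, L=3, config=FitConfig(seed=0))
print("log evidence M1 - M0:", round(comp.log_evidence_m1 - comp.log_evidence_m0, 1))
print("preferred:", comp.preferred)
```

prints

```
converged: True
mixing weights: [0.34 0.4  0.26]
classification accuracy: 1.0
log evidence M1 - M0: 14858.9
preferred: M1
```

Every sample is assigned back to its generating class (the three classes are
far apart at this depth), the fitted mixing weights match the realized class
proportions, and the evidence overwhelmingly favors the model that includes
the covariate — as it should, since the data were generated with real
effects.  The same stages are scriptable from the shell via the `enigma` CLI
(`fit`, `simulate`, `select-l`, `compare`, `evaluate`); each writes
TSV/JSON artifacts and logs its seed.

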