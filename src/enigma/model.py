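"""Core probabilistic model: a unigram (multinomial) mixture with covariate effects.

Each sample ``n`` carries taxon counts ``y_n`` (length ``K``) and binary host
properties ``x_n`` (length ``M``).  A latent class ``z_n ~ Categorical(pi)``
selects a class baseline log-abundance vector ``gamma_l``; counts are then
multinomial with probabilities ``softmax(gamma_{z_n} + x_n B)``.  The covariate
effect matrix ``B`` (``M x K``) is shared across classes, so enterotype-like
interindividual structure (the baselines) is separated from the effects of the
host properties of interest.

Priors: ``pi ~ Dirichlet(alpha)``, rows of ``B ~ N(0, sigma^2 I_K)``,
``gamma_l ~ N(0, tau^2 I_K)``, and flat priors on the scales ``sigma`` and
``tau``.  The latent classes are marginalized analytically, so the observed-data
log-likelihood is ``sum_n log sum_l pi_l Multinomial(y_n | softmax(gamma_l +
x_n B))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

#: floor applied to arguments of log to keep degenerate probabilities finite
LOG_FLOOR = 1e-300

__all__ = [
    "LOG_FLOOR",
    "OtuTable",
    "CovariateTable",
    "EnigmaParameters",
    "ParameterLayout",
    "softmax",
    "linear_predictor",
    "multinomial_loglik",
    "mixture_loglik",
    "log_prior",
    "log_posterior",
]


def softmax(v: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis.

    Subtracts the maximum before exponentiating, so the result is invariant to
    adding a constant to every entry and never overflows.

    Raises
    ------
    ValueError
        If ``v`` contains non-finite entries.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax: input must be finite")
    shifted = v - np.max(v, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


def _as_unique_labels(labels, n: int, prefix: str) -> tuple:
    if labels is None:
        return tuple(f"{prefix}{i + 1}" for i in range(n))
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if len(set(labels)) != n:
        raise ValueError(f"duplicate {prefix} identifiers")
    return labels


@dataclass(frozen=True)
class OtuTable:
    """Samples-by-taxa table of nonnegative integer read counts.

    Every sample (row) must have at least one read; identifiers must be
    unique.  ``counts`` is stored as an integer array.
    """

    counts: np.ndarray
    sample_ids: tuple = None
    taxon_ids: tuple = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples-by-taxa matrix")
        if not np.all(np.isfinite(counts.astype(float))):
            raise ValueError("counts must be finite")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        as_int = np.rint(np.asarray(counts, dtype=float)).astype(np.int64)
        if not np.allclose(np.asarray(counts, dtype=float), as_int, atol=1e-8):
            raise ValueError("counts must be integral")
        if np.any(as_int.sum(axis=1) == 0):
            raise ValueError("every sample must have at least one read")
        object.__setattr__(self, "counts", as_int)
        object.__setattr__(
            self, "sample_ids", _as_unique_labels(self.sample_ids, as_int.shape[0], "sample")
        )
        object.__setattr__(
            self, "taxon_ids", _as_unique_labels(self.taxon_ids, as_int.shape[1], "taxon")
        )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample read depth."""
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Counts divided by per-sample totals (rows sum to one)."""
        return self.counts / self.totals[:, None]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids))


@dataclass(frozen=True)
class CovariateTable:
    """Binary samples-by-covariates design matrix of host properties.

    The model's covariates are indicator variables (1 = the sample has the
    property).  Sample order must match the paired :class:`OtuTable`.
    """

    design: np.ndarray
    covariate_names: tuple = None
    sample_ids: tuple = None

    def __post_init__(self):
        design = np.asarray(self.design, dtype=float)
        if design.ndim != 2:
            raise ValueError("design must be a 2-D samples-by-covariates matrix")
        if not np.all(np.isfinite(design)):
            raise ValueError("design must be finite")
        if not np.all(np.isin(design, (0.0, 1.0))):
            raise ValueError("design entries must be 0 or 1")
        object.__setattr__(self, "design", design)
        object.__setattr__(
            self,
            "covariate_names",
            _as_unique_labels(self.covariate_names, design.shape[1], "covariate"),
        )
        object.__setattr__(
            self, "sample_ids", _as_unique_labels(self.sample_ids, design.shape[0], "sample")
        )

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.design.shape[1]


def _broadcast_alpha(alpha, L: int) -> np.ndarray:
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 0:
        a = np.full(L, float(a))
    if a.shape != (L,):
        raise ValueError(f"alpha must be a scalar or length-{L} vector")
    if np.any(a <= 0):
        raise ValueError("alpha entries must be positive")
    return a


@dataclass(frozen=True)
class EnigmaParameters:
    """Full parameter set: mixing weights, class baselines, covariate effects.

    ``pi``: length-``L`` simplex vector. ``gamma``: ``L x K`` class baseline
    logits. ``B``: ``M x K`` covariate effects (``M`` may be 0 for the
    covariate-free model). ``sigma``/``tau``: prior standard deviations of the
    rows of ``B`` and of the ``gamma_l``. ``alpha``: Dirichlet hyperparameters
    for ``pi`` (default all ones, a noninformative prior).
    """

    pi: np.ndarray
    gamma: np.ndarray
    B: np.ndarray = None
    sigma: float = 1.0
    tau: float = 1.0
    alpha: np.ndarray = None

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if pi.ndim != 1:
            raise ValueError("pi must be a vector")
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be on the simplex (nonnegative, sum 1)")
        if gamma.ndim != 2 or gamma.shape[0] != pi.shape[0]:
            raise ValueError("gamma must be L x K with L matching pi")
        B = self.B
        if B is None:
            B = np.zeros((0, gamma.shape[1]))
        B = np.asarray(B, dtype=float)
        if B.ndim != 2 or B.shape[1] != gamma.shape[1]:
            raise ValueError("B must be M x K with K matching gamma")
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")
        alpha = _broadcast_alpha(1.0 if self.alpha is None else self.alpha, pi.shape[0])
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "alpha", alpha)

    @property
    def n_classes(self) -> int:
        return self.pi.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.B.shape[0]

    def class_occurrence(self) -> np.ndarray:
        """``p'_l = softmax(gamma_l)``: taxon occurrence probabilities per class."""
        return softmax(self.gamma)


@dataclass(frozen=True)
class ParameterLayout:
    """Mapping between :class:`EnigmaParameters` and a flat unconstrained vector.

    The free parameters are: the mixing weights through a zero-anchored
    softmax (``L - 1`` entries; the first class's logit is pinned at 0), the
    ``L x K`` baselines, the ``M x K`` covariate effects, and optionally
    ``log sigma`` and ``log tau``.  ``dim`` is the free-parameter count ``D``
    used by the Laplace evidence.
    """

    L: int
    K: int
    M: int
    estimate_scales: bool = False

    @property
    def pi_slice(self) -> slice:
        return slice(0, self.L - 1)

    @property
    def gamma_slice(self) -> slice:
        return slice(self.L - 1, self.L - 1 + self.L * self.K)

    @property
    def b_slice(self) -> slice:
        start = self.L - 1 + self.L * self.K
        return slice(start, start + self.M * self.K)

    @property
    def scale_slice(self) -> slice:
        start = self.L - 1 + (self.L + self.M) * self.K
        return slice(start, start + (2 if self.estimate_scales else 0))

    @property
    def dim(self) -> int:
        return self.L - 1 + (self.L + self.M) * self.K + (2 if self.estimate_scales else 0)

    def pack(self, params: EnigmaParameters) -> np.ndarray:
        if params.n_classes != self.L or params.n_taxa != self.K or params.n_covariates != self.M:
            raise ValueError("parameter shapes do not match layout")
        theta = np.empty(self.dim)
        logpi = np.log(np.maximum(params.pi, LOG_FLOOR))
        theta[self.pi_slice] = logpi[1:] - logpi[0]
        theta[self.gamma_slice] = params.gamma.ravel()
        theta[self.b_slice] = params.B.ravel()
        if self.estimate_scales:
            theta[self.scale_slice] = np.log([params.sigma, params.tau])
        return theta

    def unpack(
        self,
        theta: np.ndarray,
        sigma: float = 1.0,
        tau: float = 1.0,
        alpha=1.0,
    ) -> EnigmaParameters:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dim,):
            raise ValueError(f"theta must have length {self.dim}")
        v = np.concatenate([[0.0], theta[self.pi_slice]])
        pi = softmax(v)
        gamma = theta[self.gamma_slice].reshape(self.L, self.K)
        B = theta[self.b_slice].reshape(self.M, self.K)
        if self.estimate_scales:
            sigma, tau = np.exp(theta[self.scale_slice])
        return EnigmaParameters(
            pi=pi, gamma=gamma, B=B, sigma=float(sigma), tau=float(tau), alpha=alpha
        )


def linear_predictor(gamma_l: np.ndarray, x_n: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-taxon logits ``gamma_l + x_n B`` for one sample.

    ``x_n`` is a length-``M`` covariate vector and ``B`` an ``M x K`` matrix,
    so covariates index the rows of ``B``.
    """
    gamma_l = np.asarray(gamma_l, dtype=float)
    x_n = np.atleast_1d(np.asarray(x_n, dtype=float))
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or x_n.shape != (B.shape[0],) or gamma_l.shape != (B.shape[1],):
        raise ValueError(
            f"shape mismatch: gamma_l {gamma_l.shape}, x_n {x_n.shape}, B {B.shape}"
        )
    return gamma_l + x_n @ B


def multinomial_loglik(
    y_n: np.ndarray, p: np.ndarray, include_constant: bool = False
) -> float:
    """Multinomial log-probability of one count vector under probabilities ``p``.

    Log arguments are floored at :data:`LOG_FLOOR`, so a positive count on a
    zero probability yields a very large negative value instead of an
    exception.  The combinatorial constant ``log(T! / prod_k y_k!)`` does not
    depend on parameters and is added only when ``include_constant`` is set.
    """
    y = np.asarray(y_n, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y_n and p must have the same shape")
    out = float(y @ np.log(np.maximum(p, LOG_FLOOR)))
    if include_constant:
        out += float(gammaln(y.sum() + 1.0) - gammaln(y + 1.0).sum())
    return out


def _log_multinomial_constant(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    return float(np.sum(gammaln(counts.sum(axis=1) + 1.0)) - np.sum(gammaln(counts + 1.0)))


def _component_logliks(
    counts: np.ndarray, design: np.ndarray, params: EnigmaParameters
) -> np.ndarray:
    """N x L matrix of per-sample, per-class multinomial log-likelihoods (no constant)."""
    counts = np.asarray(counts, dtype=float)
    if params.n_covariates:
        xb = design @ params.B
    else:
        xb = np.zeros((counts.shape[0], params.n_taxa))
    eta = params.gamma[:, None, :] + xb[None, :, :]  # (L, N, K)
    logp = eta - logsumexp(eta, axis=2, keepdims=True)
    return np.einsum("lnk,nk->nl", logp, counts)


def mixture_loglik(
    Y: OtuTable, X: CovariateTable, params: EnigmaParameters, include_constant: bool = True
) -> float:
    """Observed-data log-likelihood with the latent classes marginalized.

    ``sum_n log sum_l pi_l Multinomial(y_n | softmax(gamma_l + x_n B))``,
    with the inner sum evaluated by log-sum-exp.
    """
    counts = Y.counts
    design = X.design if X is not None else np.zeros((Y.n_samples, 0))
    if design.shape != (Y.n_samples, params.n_covariates):
        raise ValueError("covariate table does not match counts/parameters")
    if Y.n_taxa != params.n_taxa:
        raise ValueError("taxon dimension mismatch")
    m = _component_logliks(counts, design, params)
    a = m + np.log(np.maximum(params.pi, LOG_FLOOR))
    out = float(np.sum(logsumexp(a, axis=1)))
    if include_constant:
        out += _log_multinomial_constant(counts)
    return out


def log_prior(params: EnigmaParameters) -> float:
    """Log prior density: Gaussian on B rows and gamma rows, Dirichlet on pi.

    The flat priors on sigma and tau contribute a constant taken as 0.
    """
    if params.sigma <= 0 or params.tau <= 0:
        raise ValueError("sigma and tau must be positive")
    M, K = params.B.shape
    L = params.n_classes
    s2, t2 = params.sigma**2, params.tau**2
    out = -0.5 * np.sum(params.B**2) / s2 - 0.5 * M * K * np.log(2.0 * np.pi * s2)
    out += -0.5 * np.sum(params.gamma**2) / t2 - 0.5 * L * K * np.log(2.0 * np.pi * t2)
    a = params.alpha
    out += float(
        gammaln(a.sum())
        - gammaln(a).sum()
        + np.sum((a - 1.0) * np.log(np.maximum(params.pi, LOG_FLOOR)))
    )
    return float(out)


def log_posterior(
    Y: OtuTable, X: CovariateTable, params: EnigmaParameters, include_constant: bool = True
) -> float:
    """Unnormalized log posterior: mixture log-likelihood plus log prior."""
    return mixture_loglik(Y, X, params, include_constant=include_constant) + log_prior(params)
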