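"""MAP estimation, Laplace approximation, credible intervals, classification.

The posterior mode is found by L-BFGS on the unconstrained parameter vector
(mixing weights through a zero-anchored softmax, optional log scales), using a
hand-derived analytic gradient.  Uncertainty comes from a Laplace (Gaussian)
approximation at the mode: the covariance is the inverse of the Hessian of the
negative log posterior, computed by central differences of the analytic
gradient.  Mixture posteriors are multimodal, so the optimizer is restarted
from a k-means-based initializer plus jittered copies and the best mode kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .model import (
    LOG_FLOOR,
    CovariateTable,
    EnigmaParameters,
    OtuTable,
    ParameterLayout,
    _broadcast_alpha,
    _component_logliks,
    _log_multinomial_constant,
    log_posterior,
    mixture_loglik,
    softmax,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_map",
    "compute_hessian",
    "numeric_hessian",
    "regularize_hessian",
    "classify_samples",
    "credible_intervals",
    "beta_interval_arrays",
]


@dataclass(frozen=True)
class FitConfig:
    """Options for :func:`fit_map`.

    ``n_restarts`` counts optimizer starts in total: one k-means-seeded start
    plus jittered copies (baseline logits perturbed by ``N(0, jitter_sd)``).
    ``sigma``/``tau`` are the prior scales, fixed unless ``estimate_scales``
    puts them (on the log scale) into the free parameter vector.  ``gtol`` is
    a relative gradient tolerance for the convergence flag: the fit is deemed
    converged when ``||grad||_inf <= gtol * max(1, |log posterior|)``.
    """

    n_restarts: int = 5
    maxiter: int = 1000
    gtol: float = 1e-5
    seed: int = 0
    sigma: float = 1.0
    tau: float = 1.0
    alpha: float = 1.0
    estimate_scales: bool = False
    jitter_sd: float = 0.1
    compute_hessian: bool = True
    hessian_floor: float = 1e-8


@dataclass
class FitResult:
    """MAP fit with Laplace uncertainty.

    ``hessian`` is the Hessian of the NEGATIVE log posterior at the mode (so
    ``covariance = hessian^{-1}`` is positive definite after eigenvalue
    regularization); the curvature matrix in the quadratic expansion of the
    log posterior itself is its negation.  ``log_posterior`` and
    ``log_likelihood`` include the multinomial combinatorial constant.
    """

    params: EnigmaParameters
    theta: np.ndarray
    layout: ParameterLayout
    log_posterior: float
    log_likelihood: float
    responsibilities: np.ndarray
    assignments: np.ndarray
    class_occurrence: np.ndarray
    converged: bool
    grad_norm: float
    n_restarts_used: int
    seed: int
    hessian: np.ndarray = None
    covariance: np.ndarray = None
    hessian_logdet: float = None

    @property
    def n_free_parameters(self) -> int:
        return self.layout.dim


def _make_objective(counts, design, layout: ParameterLayout, alpha, sigma0, tau0):
    """Negative unnormalized log posterior and its gradient, as a closure.

    Constant terms (multinomial coefficient, Gaussian/Dirichlet normalizers)
    are dropped; they do not depend on the free parameters.
    """
    Y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    N, K = Y.shape
    L, M = layout.L, layout.M
    T = Y.sum(axis=1)
    alpha = np.asarray(alpha, dtype=float)
    a0 = alpha.sum()

    def value_and_grad(theta):
        v = np.concatenate([[0.0], theta[layout.pi_slice]])
        logpi = v - logsumexp(v)
        pi = np.exp(logpi)
        gamma = theta[layout.gamma_slice].reshape(L, K)
        B = theta[layout.b_slice].reshape(M, K)
        if layout.estimate_scales:
            logsig, logtau = theta[layout.scale_slice]
            sigma, tau = np.exp(logsig), np.exp(logtau)
        else:
            sigma, tau = sigma0, tau0

        xb = X @ B if M else np.zeros((N, K))
        eta = gamma[:, None, :] + xb[None, :, :]  # (L, N, K)
        logp = eta - logsumexp(eta, axis=2, keepdims=True)
        m = np.einsum("lnk,nk->nl", logp, Y)
        a = m + logpi
        ll_n = logsumexp(a, axis=1)
        r = np.exp(a - ll_n[:, None])  # responsibilities (N, L)

        f = float(ll_n.sum())
        f += -0.5 * np.sum(B**2) / sigma**2 - M * K * np.log(sigma)
        f += -0.5 * np.sum(gamma**2) / tau**2 - L * K * np.log(tau)
        f += float(np.sum((alpha - 1.0) * logpi))

        grad = np.empty(layout.dim)
        P = np.exp(logp)  # (L, N, K)
        rT = r * T[:, None]  # (N, L)
        g_gamma = np.einsum("nl,nk->lk", r, Y) - np.einsum("nl,lnk->lk", rT, P)
        g_gamma -= gamma / tau**2
        grad[layout.gamma_slice] = g_gamma.ravel()
        if M:
            pbar = np.einsum("nl,lnk->nk", rT, P)
            g_B = X.T @ (Y - pbar) - B / sigma**2
            grad[layout.b_slice] = g_B.ravel()
        g_v = (r - pi).sum(axis=0) + (alpha - 1.0) - pi * (a0 - L)
        grad[layout.pi_slice] = g_v[1:]
        if layout.estimate_scales:
            grad[layout.scale_slice] = [
                np.sum(B**2) / sigma**2 - M * K,
                np.sum(gamma**2) / tau**2 - L * K,
            ]
        return -f, -grad

    return value_and_grad


def _kmeans_init(counts, L: int, random_state: int) -> np.ndarray:
    """Cluster log relative abundances (pseudo-count 0.5) to seed the mixture."""
    from sklearn.cluster import KMeans

    rel = counts + 0.5
    rel = rel / rel.sum(axis=1, keepdims=True)
    feats = np.log(rel)
    if L == 1:
        return np.zeros(counts.shape[0], dtype=int)
    km = KMeans(n_clusters=L, n_init=4, random_state=random_state)
    return km.fit_predict(feats)


def _initial_params(counts, L: int, layout: ParameterLayout, config: FitConfig, rng) -> list:
    N, K = counts.shape
    labels = _kmeans_init(counts, L, int(rng.integers(2**31 - 1)))
    pooled = counts.sum(axis=0) + 0.5
    pooled = pooled / pooled.sum()
    gamma0 = np.empty((L, K))
    pi0 = np.empty(L)
    for l in range(L):
        mask = labels == l
        pi0[l] = max(mask.sum(), 0.5) / N
        if mask.any():
            p = counts[mask].sum(axis=0) + 0.5
            p = p / p.sum()
        else:
            p = pooled
        g = np.log(p)
        gamma0[l] = g - g.mean()
    pi0 = pi0 / pi0.sum()

    inits = []
    for restart in range(config.n_restarts):
        gamma_r = gamma0 if restart == 0 else gamma0 + rng.normal(0.0, config.jitter_sd, gamma0.shape)
        params = EnigmaParameters(
            pi=pi0,
            gamma=gamma_r,
            B=np.zeros((layout.M, K)),
            sigma=config.sigma,
            tau=config.tau,
            alpha=_broadcast_alpha(config.alpha, L),
        )
        inits.append(layout.pack(params))
    return inits


def fit_map(Y: OtuTable, X: CovariateTable, L: int, config: FitConfig = None) -> FitResult:
    """Find the MAP estimate for an ``L``-class mixture by multi-start L-BFGS.

    ``X`` may be ``None`` for the covariate-free model (all covariate effects
    pinned at zero, removing them from the free parameters).  Deterministic
    given ``config.seed``.  Non-convergence is reported through the
    ``converged`` flag, never as an exception.
    """
    config = config or FitConfig()
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > Y.n_samples:
        raise ValueError("L must not exceed the number of samples")
    counts = Y.counts.astype(float)
    design = X.design if X is not None else np.zeros((Y.n_samples, 0))
    if design.shape[0] != Y.n_samples:
        raise ValueError("covariate table and count table have different sample counts")
    N, K = counts.shape
    M = design.shape[1]
    layout = ParameterLayout(L=L, K=K, M=M, estimate_scales=config.estimate_scales)
    alpha = _broadcast_alpha(config.alpha, L)
    objective = _make_objective(counts, design, layout, alpha, config.sigma, config.tau)

    rng = np.random.default_rng(config.seed)
    inits = _initial_params(counts, L, layout, config, rng)
    best = None
    for theta0 in inits:
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    _, neg_grad = objective(theta_hat)
    grad_norm = float(np.max(np.abs(neg_grad)))
    params_hat = layout.unpack(theta_hat, sigma=config.sigma, tau=config.tau, alpha=alpha)
    lp_mode = log_posterior(Y, X, params_hat)
    converged = grad_norm <= config.gtol * max(1.0, abs(lp_mode))

    responsibilities, assignments = classify_samples(Y, X, params_hat)
    result = FitResult(
        params=params_hat,
        theta=theta_hat,
        layout=layout,
        log_posterior=lp_mode,
        log_likelihood=mixture_loglik(Y, X, params_hat),
        responsibilities=responsibilities,
        assignments=assignments,
        class_occurrence=params_hat.class_occurrence(),
        converged=converged,
        grad_norm=grad_norm,
        n_restarts_used=len(inits),
        seed=config.seed,
    )
    if config.compute_hessian:
        H = compute_hessian(Y, X, params_hat, estimate_scales=config.estimate_scales)
        Hreg, cov, logdet = regularize_hessian(H, floor_ratio=config.hessian_floor)
        result.hessian = Hreg
        result.covariance = cov
        result.hessian_logdet = logdet
    return result


def compute_hessian(
    Y: OtuTable,
    X: CovariateTable,
    params: EnigmaParameters,
    method: str = "central_difference",
    estimate_scales: bool = False,
    step_scale: float = 1e-5,
    grad_tol: float = 1e-3,
) -> np.ndarray:
    """Hessian of the negative log posterior at ``params``.

    ``central_difference`` (default) differences the analytic gradient, which
    is accurate to roughly the square of the step; ``objective`` uses second
    differences of the objective itself and serves as an independent
    cross-check on small problems.  Warns if ``params`` is not approximately
    stationary.
    """
    counts = Y.counts.astype(float)
    design = X.design if X is not None else np.zeros((Y.n_samples, 0))
    layout = ParameterLayout(
        L=params.n_classes, K=params.n_taxa, M=params.n_covariates, estimate_scales=estimate_scales
    )
    objective = _make_objective(counts, design, layout, params.alpha, params.sigma, params.tau)
    theta = layout.pack(params)
    _, g0 = objective(theta)
    if np.max(np.abs(g0)) > grad_tol * max(1.0, abs(objective(theta)[0])):
        warnings.warn(
            f"Hessian requested away from a stationary point (|grad|_inf={np.max(np.abs(g0)):.3g})",
            stacklevel=2,
        )
    if method == "central_difference":
        grad = lambda t: objective(t)[1]
        return hessian_from_gradient(grad, theta, step_scale=step_scale)
    if method == "objective":
        fun = lambda t: objective(t)[0]
        return numeric_hessian(fun, theta)
    raise ValueError(f"unknown Hessian method: {method!r}")


def hessian_from_gradient(grad, theta: np.ndarray, step_scale: float = 1e-5) -> np.ndarray:
    """Central differences of a gradient function; symmetrized on return."""
    theta = np.asarray(theta, dtype=float)
    D = theta.size
    H = np.empty((D, D))
    for j in range(D):
        h = step_scale * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        H[:, j] = (grad(tp) - grad(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def numeric_hessian(fun, theta: np.ndarray, step_scale: float = 1e-4) -> np.ndarray:
    """Second differences of a scalar function (for toys and cross-checks)."""
    theta = np.asarray(theta, dtype=float)
    D = theta.size
    h = step_scale * (1.0 + np.abs(theta))
    H = np.empty((D, D))
    f0 = fun(theta)
    for i in range(D):
        ei = np.zeros(D)
        ei[i] = h[i]
        H[i, i] = (fun(theta + ei) - 2.0 * f0 + fun(theta - ei)) / h[i] ** 2
        for j in range(i + 1, D):
            ej = np.zeros(D)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej) - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def regularize_hessian(H: np.ndarray, floor_ratio: float = 1e-8):
    """Floor near-zero eigenvalues of a (nominally SPD) Hessian before inversion.

    Softmax over-parameterization can leave nearly flat directions despite the
    priors; eigenvalues below ``floor_ratio`` times the largest are raised to
    that threshold (with a logged warning).  Returns the regularized Hessian,
    its inverse (the Laplace covariance) and its log-determinant.

    Raises
    ------
    ValueError
        If the largest eigenvalue is not positive (no amount of flooring makes
        the matrix a credible curvature matrix); the eigenvalues are reported.
    """
    H = 0.5 * (np.asarray(H, dtype=float) + np.asarray(H, dtype=float).T)
    w, V = np.linalg.eigh(H)
    wmax = w[-1]
    if wmax <= 0:
        raise ValueError(f"Hessian is not positive definite; eigenvalues: {w}")
    floor = floor_ratio * wmax
    n_floored = int(np.sum(w < floor))
    if n_floored:
        logger.warning("floored %d Hessian eigenvalues below %.3g", n_floored, floor)
    w = np.maximum(w, floor)
    Hreg = (V * w) @ V.T
    cov = (V / w) @ V.T
    return Hreg, 0.5 * (cov + cov.T), float(np.sum(np.log(w)))


def classify_samples(Y: OtuTable, X: CovariateTable, params: EnigmaParameters):
    """Posterior class probabilities and hard assignments for each sample.

    ``responsibilities[n, l] = pi_l p(y_n | gamma_l, B, x_n) / sum_l' ...``,
    computed in log space; assignments break ties toward the smallest index.
    """
    counts = Y.counts.astype(float)
    design = X.design if X is not None else np.zeros((Y.n_samples, 0))
    m = _component_logliks(counts, design, params)
    a = m + np.log(np.maximum(params.pi, LOG_FLOOR))
    r = np.exp(a - logsumexp(a, axis=1, keepdims=True))
    r = r / r.sum(axis=1, keepdims=True)
    return r, np.argmax(r, axis=1)


def _interval_bounds(theta, sd, level):
    z = norm.ppf(0.5 * (1.0 + level))
    return theta - z * sd, theta + z * sd


def credible_intervals(
    fit: FitResult, level: float = 0.95, targets=("B", "gamma")
) -> pd.DataFrame:
    """Per-coefficient Laplace credible intervals as a tidy table.

    For ``B`` and ``gamma`` the interval is ``theta_hat_j +/- z sqrt(cov_jj)``.
    For ``class_occurrence`` the gamma interval endpoints are mapped through
    the softmax coordinate-wise (the other coordinates held at the MAP).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if fit.covariance is None:
        raise ValueError("fit has no covariance; rerun with compute_hessian=True")
    layout = fit.layout
    sd_all = np.sqrt(np.maximum(np.diag(fit.covariance), 0.0))
    rows = []
    if "B" in targets and layout.M:
        est = fit.theta[layout.b_slice].reshape(layout.M, layout.K)
        sd = sd_all[layout.b_slice].reshape(layout.M, layout.K)
        lo, hi = _interval_bounds(est, sd, level)
        for m in range(layout.M):
            for k in range(layout.K):
                rows.append(("B", m, k, est[m, k], sd[m, k], lo[m, k], hi[m, k]))
    if "gamma" in targets:
        est = fit.theta[layout.gamma_slice].reshape(layout.L, layout.K)
        sd = sd_all[layout.gamma_slice].reshape(layout.L, layout.K)
        lo, hi = _interval_bounds(est, sd, level)
        for l in range(layout.L):
            for k in range(layout.K):
                rows.append(("gamma", l, k, est[l, k], sd[l, k], lo[l, k], hi[l, k]))
    if "class_occurrence" in targets:
        gamma = fit.params.gamma
        sd = sd_all[layout.gamma_slice].reshape(layout.L, layout.K)
        glo, ghi = _interval_bounds(gamma, sd, level)
        occ = fit.class_occurrence
        for l in range(layout.L):
            for k in range(layout.K):
                glo_vec = gamma[l].copy()
                glo_vec[k] = glo[l, k]
                ghi_vec = gamma[l].copy()
                ghi_vec[k] = ghi[l, k]
                rows.append(
                    (
                        "class_occurrence",
                        l,
                        k,
                        occ[l, k],
                        np.nan,
                        softmax(glo_vec)[k],
                        softmax(ghi_vec)[k],
                    )
                )
    out = pd.DataFrame(
        rows, columns=["target", "row", "taxon", "estimate", "sd", "lower", "upper"]
    )
    out["level"] = level
    return out


def beta_interval_arrays(fit: FitResult, level: float = 0.95):
    """Covariate-effect interval endpoints as ``(lower, upper)`` M x K arrays."""
    layout = fit.layout
    est = fit.theta[layout.b_slice].reshape(layout.M, layout.K)
    sd = np.sqrt(np.maximum(np.diag(fit.covariance)[layout.b_slice], 0.0)).reshape(
        layout.M, layout.K
    )
    return _interval_bounds(est, sd, level)
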