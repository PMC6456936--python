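"""Model comparison by Laplace evidence and cluster-number selection.

Two model-choice questions arise: (i) do the covariates matter at all —
compared by the Laplace-approximate log marginal likelihood of the full model
(M1) against the model with all covariate effects pinned at zero (M0); and
(ii) how many latent classes — chosen by maximizing the Calinski-Harabasz
index over a divergence matrix between the samples' relative-abundance
profiles.

The divergence used for (ii) follows the enterotyping convention: a
symmetrized Kullback-Leibler form evaluated on normalized abundances after
replacing zeros with a 1e-6 pseudo-count.  The textbook Jensen-Shannon
divergence (KL to the midpoint mixture) is available behind ``variant``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import FitConfig, FitResult, fit_map
from .model import CovariateTable, OtuTable

__all__ = [
    "ModelComparison",
    "ClusterSelection",
    "laplace_evidence",
    "log_marginal_likelihood",
    "compare_models",
    "jsd",
    "jsd_matrix",
    "ch_index",
    "select_num_clusters",
]


@dataclass(frozen=True)
class ModelComparison:
    """Evidence comparison of the covariate model (M1) against the null (M0)."""

    log_evidence_m1: float
    log_evidence_m0: float
    d_m1: int
    d_m0: int

    @property
    def preferred(self) -> str:
        return "M1" if self.log_evidence_m1 > self.log_evidence_m0 else "M0"


@dataclass(frozen=True)
class ClusterSelection:
    """CH-index values over candidate class counts and the maximizing choice.

    A degenerate candidate (zero within-cluster dispersion) has an infinite CH
    index; ``ch_values`` stores it as the largest finite float with the
    corresponding ``degenerate`` flag set, so it still wins the argmax without
    propagating infinities downstream.
    """

    candidate_L: tuple
    ch_values: tuple
    chosen_L: int
    labels_per_L: dict
    degenerate: tuple


def laplace_evidence(log_joint_at_mode: float, neg_hessian: np.ndarray) -> float:
    """Laplace approximation to a log evidence from the mode and curvature.

    ``log_joint_at_mode`` is the log of the unnormalized posterior (likelihood
    times prior) at its maximum and ``neg_hessian`` the Hessian of its
    negative log there; the Gaussian integral gives
    ``log_joint + (D/2) log 2 pi - (1/2) log |H|``.  Exact when the joint is
    Gaussian in the parameters.
    """
    H = np.asarray(neg_hessian, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("neg_hessian must be square")
    D = H.shape[0]
    w = np.linalg.eigvalsh(0.5 * (H + H.T))
    if w[0] <= 0:
        raise ValueError(f"Hessian not positive definite; eigenvalues: {w}")
    return float(log_joint_at_mode + 0.5 * D * np.log(2.0 * np.pi) - 0.5 * np.sum(np.log(w)))


def log_marginal_likelihood(fit: FitResult) -> float:
    """Laplace log marginal likelihood of a fitted mixture.

    Uses the (regularized) negative-log-posterior Hessian stored in the fit;
    the log posterior at the mode includes the multinomial constant, which is
    shared by models fitted to the same table and cancels in comparisons.
    """
    if fit.hessian_logdet is None:
        raise ValueError("fit has no Hessian; rerun with compute_hessian=True")
    D = fit.n_free_parameters
    return float(fit.log_posterior + 0.5 * D * np.log(2.0 * np.pi) - 0.5 * fit.hessian_logdet)


def compare_models(
    Y: OtuTable, X: CovariateTable, L: int, config: FitConfig = None
) -> ModelComparison:
    """Fit M1 (free covariate effects) and M0 (effects pinned at zero); compare.

    The free-parameter count of M0 drops by ``M x K`` accordingly; the larger
    log marginal likelihood wins.
    """
    if X is None:
        raise ValueError("compare_models requires a covariate table")
    fit1 = fit_map(Y, X, L, config)
    fit0 = fit_map(Y, None, L, config)
    return ModelComparison(
        log_evidence_m1=log_marginal_likelihood(fit1),
        log_evidence_m0=log_marginal_likelihood(fit0),
        d_m1=fit1.n_free_parameters,
        d_m0=fit0.n_free_parameters,
    )


def _prepare_composition(a, pseudo: float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or np.any(~np.isfinite(a)) or np.any(a < 0) or a.sum() <= 0:
        raise ValueError("input must be a nonnegative, normalizable vector")
    a = a / a.sum()
    a = np.where(a <= 0, pseudo, a)
    return a / a.sum()


def jsd(a, b, pseudo: float = 1e-6, variant: str = "symmetrized_kl") -> float:
    """Divergence between two composition vectors.

    ``symmetrized_kl`` (default) is
    ``(1/2)[sum_k a_k log(a_k/b_k) + sum_k b_k log(b_k/a_k)]``; zeros are
    replaced by ``pseudo`` and the vectors renormalized first.  ``variant=
    "jensen_shannon"`` gives the bounded textbook form with the midpoint
    mixture.  Symmetric, nonnegative, zero iff the prepared vectors coincide.
    """
    a = _prepare_composition(a, pseudo)
    b = _prepare_composition(b, pseudo)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if variant == "symmetrized_kl":
        return float(0.5 * np.sum((a - b) * (np.log(a) - np.log(b))))
    if variant == "jensen_shannon":
        m = 0.5 * (a + b)
        return float(0.5 * (np.sum(a * np.log(a / m)) + np.sum(b * np.log(b / m))))
    raise ValueError(f"unknown variant: {variant!r}")


def jsd_matrix(
    profiles: np.ndarray, pseudo: float = 1e-6, variant: str = "symmetrized_kl"
) -> np.ndarray:
    """Pairwise divergence matrix of N composition rows (vectorized)."""
    P = np.stack([_prepare_composition(row, pseudo) for row in np.asarray(profiles, dtype=float)])
    logP = np.log(P)
    if variant == "symmetrized_kl":
        t = np.sum(P * logP, axis=1)
        C = P @ logP.T
        D = 0.5 * (t[:, None] + t[None, :] - C - C.T)
    elif variant == "jensen_shannon":
        N = P.shape[0]
        D = np.zeros((N, N))
        for i in range(N):
            for j in range(i + 1, N):
                D[i, j] = D[j, i] = jsd(P[i], P[j], pseudo=pseudo, variant=variant)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def ch_index(distances: np.ndarray, labels: np.ndarray, L: int = None) -> float:
    """Calinski-Harabasz index over a precomputed squared-distance matrix.

    ``BC`` sums the entries over pairs in different clusters and ``WC`` over
    pairs in the same cluster (each unordered pair once); the index is
    ``(BC/(L-1)) / (WC/(N-L))``.  The divergence values are used directly as
    the squared distances.  Returns ``inf`` when ``WC`` is zero (e.g. all
    singleton clusters).
    """
    D = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    N = labels.shape[0]
    if D.shape != (N, N):
        raise ValueError("distance matrix and labels disagree on N")
    uniq = np.unique(labels)
    if L is None:
        L = uniq.size
    if L < 2:
        raise ValueError("CH index requires at least 2 clusters")
    if uniq.size != L:
        raise ValueError(f"expected {L} nonempty clusters, found {uniq.size}")
    iu, ju = np.triu_indices(N, k=1)
    same = labels[iu] == labels[ju]
    wc = float(D[iu, ju][same].sum())
    bc = float(D[iu, ju][~same].sum())
    if wc == 0.0:
        return float("inf")
    return (bc / (L - 1)) / (wc / (N - L))


def _pam(D: np.ndarray, L: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Plain k-medoids (PAM-style alternation) on a precomputed distance matrix."""
    rng = np.random.default_rng(seed)
    N = D.shape[0]
    medoids = rng.choice(N, size=L, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for l in range(L):
            members = np.flatnonzero(labels == l)
            if members.size == 0:
                new_medoids[l] = rng.integers(N)
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[l] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def select_num_clusters(
    Y: OtuTable,
    X: CovariateTable = None,
    candidate_L=(2, 3, 4, 5),
    config: FitConfig = None,
    method: str = "mixture",
    variant: str = "symmetrized_kl",
    pseudo: float = 1e-6,
) -> ClusterSelection:
    """Choose the number of latent classes by maximizing the CH index.

    The divergence matrix over normalized abundances is computed once.  For
    each candidate ``L`` the labels come either from the covariate-free
    mixture fit (``method="mixture"``, the default — selection stays internal
    to the model) or from k-medoids on the divergence matrix
    (``method="kmedoids"``, the classical enterotyping workflow).
    """
    candidate_L = tuple(int(l) for l in candidate_L)
    if any(l < 2 for l in candidate_L):
        raise ValueError("candidate class counts must be >= 2")
    config = config or FitConfig()
    D = jsd_matrix(Y.relative_abundances(), pseudo=pseudo, variant=variant)
    ch_values, degenerate, labels_per_L = [], [], {}
    for L in candidate_L:
        if method == "mixture":
            cfg = FitConfig(
                n_restarts=config.n_restarts,
                maxiter=config.maxiter,
                seed=config.seed + L,
                sigma=config.sigma,
                tau=config.tau,
                alpha=config.alpha,
                compute_hessian=False,
            )
            labels = fit_map(Y, None, L, cfg).assignments
        elif method == "kmedoids":
            labels = _pam(D, L, seed=config.seed + L)
        else:
            raise ValueError(f"unknown method: {method!r}")
        labels_per_L[L] = labels
        # collapse to the realized number of clusters if some are empty
        realized = np.unique(labels).size
        if realized < 2:
            ch, degen = -np.inf, False
        else:
            ch = ch_index(D, labels, L=realized)
            degen = not np.isfinite(ch)
            if degen:
                ch = np.finfo(float).max
        ch_values.append(float(ch))
        degenerate.append(degen)
    chosen = candidate_L[int(np.argmax(ch_values))]
    return ClusterSelection(
        candidate_L=candidate_L,
        ch_values=tuple(ch_values),
        chosen_L=chosen,
        labels_per_L=labels_per_L,
        degenerate=tuple(degenerate),
    )
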