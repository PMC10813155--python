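"""Parameter estimation: K-means initialization and Baum-Welch EM.

Training follows the protocol used for the balance-control classifier:
K-means seeds the Gaussian parameters, then a fixed number of EM iterations
(default 15, with 3 states and 2 mixture components per state) refines the
full model by maximizing the training log-likelihood.  Multiple recordings
are handled by the standard multi-sequence form of Baum-Welch: expected
sufficient statistics are summed across sequences, the initial distribution
is estimated from first-sample posteriors averaged over sequences, and
sequence boundaries are respected (no artificial transitions between
subjects).

The Gaussian M-step is the posterior-weighted mean/covariance update

    mu_k    <- sum_i tau_ik x_i / sum_i tau_ik
    Sigma_k <- sum_i tau_ik (x_i - mu_k)(x_i - mu_k)^T / sum_i tau_ik

generalized to mixtures by replacing tau_ik with per-component
responsibilities; mixture weights are the normalized component posterior
mass.  Covariances are floored (eigenvalue clip at
covariance_floor_scale x pooled data variance) after every update so EM on
short or starved segments cannot produce singular emissions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .errors import ModelValidityError, StarvedStateError
from .hmm import (
    GaussianHMM,
    GaussianMixtureEmission,
    MarkovChainParams,
    ObservationSequence,
    PosteriorSet,
    forward_backward,
    log_component_densities,
)

_STARVE_TOL = 1e-10


@dataclass
class FitConfig:
    """Training hyperparameters.

    Defaults are the protocol settings: 3 states, 2 Gaussian mixtures per
    state, 15 EM iterations run to completion (tol = 0 disables early
    stopping).
    """

    n_states: int = 3
    n_components: int = 2
    n_iter: int = 15
    tol: float = 0.0
    covariance_floor_scale: float = 1e-6
    seed: int = 0
    kmeans_restarts: int = 5

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_components < 1 or self.n_iter < 1:
            raise ValueError("n_states, n_components and n_iter must be positive")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.covariance_floor_scale <= 0:
            raise ValueError("covariance_floor_scale must be positive")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be positive")


@dataclass
class FitReport:
    """Per-iteration training log-likelihood and stopping diagnostics."""

    loglik_trajectory: List[float] = field(default_factory=list)
    n_iter_run: int = 0
    converged_by_tol: bool = False


def _pooled_values(sequences: Sequence[ObservationSequence]) -> np.ndarray:
    if not sequences:
        raise ValueError("at least one training sequence is required")
    d = sequences[0].d
    for s in sequences:
        if s.d != d:
            raise ModelValidityError(
                f"sequences mix dimensions {d} and {s.d}"
            )
    return np.vstack([s.values for s in sequences])


def _floor_covariance(S: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrize and clip eigenvalues from below at ``floor``."""
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= floor:
        return S
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def covariance_floor(
    sequences: Sequence[ObservationSequence], scale: float
) -> float:
    """Eigenvalue floor: ``scale`` times the pooled per-channel variance."""
    X = _pooled_values(sequences)
    pooled_var = float(np.mean(np.var(X, axis=0)))
    if pooled_var == 0.0:
        pooled_var = 1.0  # constant data: fall back to an absolute floor
    return scale * pooled_var


def kmeans_init(
    sequences: Sequence[ObservationSequence], config: FitConfig
) -> GaussianHMM:
    """Seed a Gaussian HMM from K-means clusters of the pooled samples.

    All samples from all sequences are pooled and clustered into
    n_states x n_components centroids (best of ``kmeans_restarts`` by
    inertia).  Centroids are ordered lexicographically for determinism and
    assigned to states in contiguous blocks of n_components; each component
    gets the centroid as mean, the within-cluster covariance (floored) and a
    weight proportional to cluster size within its state.  pi and A start
    uniform.
    """
    X = _pooled_values(sequences)
    K, C = config.n_states, config.n_components
    n_clusters = K * C
    if X.shape[0] < n_clusters:
        raise ValueError(
            f"need at least n_states x n_components = {n_clusters} samples, "
            f"got {X.shape[0]}"
        )
    floor = covariance_floor(sequences, config.covariance_floor_scale)
    if n_clusters == 1:
        labels = np.zeros(X.shape[0], dtype=int)
        centers = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(
            n_clusters=n_clusters,
            n_init=config.kmeans_restarts,
            random_state=config.seed % (2**31),
        ).fit(X)
        # relabel clusters in lexicographic centroid order so the init is a
        # pure function of (data, seed), not of sklearn's internal ordering
        order = np.lexsort(km.cluster_centers_.T[::-1])
        centers = km.cluster_centers_[order]
        inv = np.empty(n_clusters, dtype=int)
        inv[order] = np.arange(n_clusters)
        labels = inv[km.labels_]

    d = X.shape[1]
    emissions = []
    for k in range(K):
        means = np.empty((C, d))
        covs = np.empty((C, d, d))
        sizes = np.empty(C)
        for j in range(C):
            c = k * C + j
            mask = labels == c
            sizes[j] = max(mask.sum(), 1)
            means[j] = centers[c]
            if mask.sum() > 0:
                dev = X[mask] - means[j]
                S = dev.T @ dev / mask.sum()
            else:
                S = np.zeros((d, d))
            covs[j] = _floor_covariance(S, floor)
        emissions.append(
            GaussianMixtureEmission(
                weights=sizes / sizes.sum(), means=means, covariances=covs
            )
        )
    chain = MarkovChainParams(
        K=K, A=np.full((K, K), 1.0 / K), pi=np.full(K, 1.0 / K)
    )
    return GaussianHMM(chain=chain, d=d, emissions=emissions)


def m_step_single_gaussian(
    posteriors: PosteriorSet,
    seq: ObservationSequence,
    k: int,
    floor: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted mean/covariance update for state ``k`` (one
    Gaussian per state).

    Returns (mu_k, Sigma_k) with the biased (posterior-mass) normalization;
    ``floor`` optionally clips covariance eigenvalues.
    """
    tau = posteriors.gamma[:, k]
    mass = tau.sum()
    if mass < _STARVE_TOL:
        raise StarvedStateError(
            f"state {k} has posterior mass {mass:.3e} < {_STARVE_TOL}"
        )
    X = seq.values
    mu = (tau[:, None] * X).sum(axis=0) / mass
    dev = X - mu
    S = (tau[:, None] * dev).T @ dev / mass
    if floor > 0:
        S = _floor_covariance(S, floor)
    return mu, S


def _e_step(
    model: GaussianHMM, sequences: Sequence[ObservationSequence]
) -> Tuple[dict, float]:
    """Accumulate expected sufficient statistics over all sequences."""
    K, C, d = model.K, model.n_components, model.d
    stats = {
        "pi": np.zeros(K),
        "xi": np.zeros((K, K)),
        "mass": np.zeros((K, C)),         # sum_i r_ikc
        "mx": np.zeros((K, C, d)),        # sum_i r_ikc x_i
        "mxx": np.zeros((K, C, d, d)),    # sum_i r_ikc x_i x_i^T
    }
    total_ll = 0.0
    for seq in sequences:
        post = forward_backward(model, seq)
        total_ll += post.loglik
        stats["pi"] += post.gamma[0]
        stats["xi"] += post.xi_sum
        X = seq.values
        r = post.comp_gamma  # (n, K, C)
        stats["mass"] += r.sum(axis=0)
        stats["mx"] += np.einsum("ikc,id->kcd", r, X)
        stats["mxx"] += np.einsum("ikc,id,ie->kcde", r, X, X)
    return stats, total_ll


def _m_step(
    model: GaussianHMM,
    stats: dict,
    sequences: Sequence[ObservationSequence],
    floor: float,
) -> GaussianHMM:
    K, C, d = model.K, model.n_components, model.d
    n_seq = len(sequences)
    pi = stats["pi"] / n_seq
    pi = pi / pi.sum()
    A = stats["xi"].copy()
    row = A.sum(axis=1, keepdims=True)
    # a state never left keeps a uniform outgoing row rather than 0/0
    dead = row[:, 0] <= 0
    A[dead] = 1.0
    row = A.sum(axis=1, keepdims=True)
    A = A / row

    mass = stats["mass"].copy()
    mx = stats["mx"].copy()
    mxx = stats["mxx"].copy()

    starved = np.argwhere(mass < _STARVE_TOL)
    if starved.size:
        X = np.vstack([s.values for s in sequences])
        # re-seed each starved component at the sample the current model
        # explains worst (lowest best-component log density)
        dens = np.full(X.shape[0], np.inf)
        offset = 0
        for seq in sequences:
            comp = log_component_densities(model, seq)
            dens[offset : offset + seq.n] = comp.max(axis=(1, 2))
            offset += seq.n
        for k, c in starved:
            warnings.warn(
                f"re-seeding starved component (state {k}, component {c})",
                RuntimeWarning,
                stacklevel=2,
            )
            i = int(np.argmin(dens))
            dens[i] = np.inf  # don't reuse the same sample twice
            mass[k, c] = 1.0
            mx[k, c] = X[i]
            mxx[k, c] = np.outer(X[i], X[i]) + np.eye(d) * max(floor, 1e-6)

    emissions = []
    for k in range(K):
        w = mass[k] / mass[k].sum()
        means = mx[k] / mass[k][:, None]
        covs = np.empty((C, d, d))
        for c in range(C):
            S = mxx[k, c] / mass[k, c] - np.outer(means[c], means[c])
            covs[c] = _floor_covariance(S, floor)
        emissions.append(
            GaussianMixtureEmission(weights=w, means=means, covariances=covs)
        )
    chain = MarkovChainParams(K=K, A=A, pi=pi, order=model.chain.order)
    return GaussianHMM(chain=chain, d=d, emissions=emissions)


def baum_welch_fit(
    init: GaussianHMM,
    sequences: Sequence[ObservationSequence],
    config: FitConfig,
) -> Tuple[GaussianHMM, FitReport]:
    """Run Baum-Welch EM from ``init`` and return the refined model.

    Runs ``config.n_iter`` E/M iterations (stopping early only when
    ``config.tol`` > 0 and the total log-likelihood improves by less).  The
    reported trajectory entry q is the log-likelihood of the parameters at
    the start of iteration q, so it is non-decreasing by the EM guarantee.
    """
    _pooled_values(sequences)  # validates shared dimension
    floor = covariance_floor(sequences, config.covariance_floor_scale)
    model = init.copy()
    report = FitReport()
    prev_ll = -np.inf
    for q in range(config.n_iter):
        stats, total_ll = _e_step(model, sequences)
        if not np.isfinite(total_ll):
            raise ModelValidityError(
                f"non-finite log-likelihood at EM iteration {q}"
            )
        report.loglik_trajectory.append(total_ll)
        report.n_iter_run = q + 1
        if config.tol > 0 and q > 0 and total_ll - prev_ll < config.tol:
            report.converged_by_tol = True
            break
        prev_ll = total_ll
        model = _m_step(model, stats, sequences, floor)
    return model, report


def fit_gaussian_hmm(
    sequences: Sequence[ObservationSequence], config: FitConfig
) -> Tuple[GaussianHMM, FitReport]:
    """Convenience wrapper: K-means init followed by Baum-Welch."""
    init = kmeans_init(sequences, config)
    return baum_welch_fit(init, sequences, config)
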