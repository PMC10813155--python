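"""Hidden Markov model types and exact inference.

The model of interest is a first-order hidden Markov chain whose states emit
real-valued center-of-pressure displacements through Gaussian or
Gaussian-mixture densities.  This module holds the parameter containers,
likelihood evaluation (scaled forward recursion, with a pure log-space
variant for cross-checking), the forward-backward smoother that produces the
EM sufficient statistics, Viterbi decoding, ancestral sampling, and a
brute-force path-enumeration likelihood used as a test oracle.

Probabilities over minute-long recordings underflow double precision by
hundreds of orders of magnitude, so every public routine works with log
densities and per-step rescaling; raw probability products are never formed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from . import _kernels
from .errors import (
    DimensionMismatchError,
    ModelValidityError,
    SequenceError,
)

_SIMPLEX_TOL = 1e-12


def _check_simplex(v: np.ndarray, name: str, tol: float = _SIMPLEX_TOL) -> None:
    if np.any(v < -tol) or np.any(v > 1 + tol):
        raise ModelValidityError(f"{name} has entries outside [0, 1]: {v}")
    s = v.sum(axis=-1)
    if not np.allclose(s, 1.0, rtol=0, atol=1e-9):
        raise ModelValidityError(f"{name} rows must sum to 1, got {s}")


@dataclass
class MarkovChainParams:
    """First-order Markov chain over K hidden states.

    ``order`` records the chain order p; only p = 1 is supported by the
    inference routines, higher orders are representable but rejected.
    """

    K: int
    A: np.ndarray
    pi: np.ndarray
    order: int = 1

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.K < 1:
            raise ModelValidityError(f"K must be positive, got {self.K}")
        if self.order < 1:
            raise ModelValidityError(f"order must be positive, got {self.order}")
        if self.A.shape != (self.K, self.K):
            raise ModelValidityError(
                f"A must be {self.K}x{self.K}, got {self.A.shape}"
            )
        if self.pi.shape != (self.K,):
            raise ModelValidityError(
                f"pi must have length {self.K}, got {self.pi.shape}"
            )
        _check_simplex(self.A, "transition matrix A")
        _check_simplex(self.pi, "initial distribution pi")

    def require_first_order(self) -> None:
        if self.order != 1:
            raise ModelValidityError(
                f"inference supports first-order chains only (order={self.order})"
            )

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of A via the unit left eigenvector."""
        vals, vecs = np.linalg.eig(self.A.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()


@dataclass
class DiscreteHMMParams:
    """Discrete-alphabet HMM: chain plus a K x M emission probability table."""

    chain: MarkovChainParams
    M: int
    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (self.chain.K, self.M):
            raise ModelValidityError(
                f"B must be {self.chain.K}x{self.M}, got {self.B.shape}"
            )
        _check_simplex(self.B, "emission matrix B")


@dataclass
class GaussianMixtureEmission:
    """Per-state Gaussian mixture: weights (C,), means (C, d), covariances (C, d, d).

    A single component (C = 1, weight 1) is the plain Gaussian emission case.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        C, d = self.means.shape
        if self.weights.shape != (C,):
            raise ModelValidityError(
                f"weights shape {self.weights.shape} != ({C},)"
            )
        if self.covariances.shape != (C, d, d):
            raise ModelValidityError(
                f"covariances shape {self.covariances.shape} != ({C}, {d}, {d})"
            )
        _check_simplex(self.weights, "mixture weights")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def cholesky_factors(self) -> np.ndarray:
        """Lower Cholesky factor per component; raises if not positive definite."""
        C, d, _ = self.covariances.shape
        L = np.empty_like(self.covariances)
        for j in range(C):
            S = self.covariances[j]
            if not np.allclose(S, S.T, rtol=0, atol=1e-8):
                raise ModelValidityError(f"covariance {j} is not symmetric")
            try:
                L[j] = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as exc:
                raise ModelValidityError(
                    f"covariance of component {j} is not positive definite"
                ) from exc
        return L

    def min_eigenvalue(self) -> float:
        return float(
            min(np.linalg.eigvalsh(S).min() for S in self.covariances)
        )


@dataclass
class GaussianHMM:
    """Full model: hidden chain plus K Gaussian-mixture emission densities."""

    chain: MarkovChainParams
    d: int
    emissions: list  # list[GaussianMixtureEmission], length K

    def __post_init__(self) -> None:
        if len(self.emissions) != self.chain.K:
            raise ModelValidityError(
                f"need {self.chain.K} emission distributions, got {len(self.emissions)}"
            )
        n_comp = self.emissions[0].n_components
        for k, em in enumerate(self.emissions):
            if em.d != self.d:
                raise ModelValidityError(
                    f"emission {k} has dimension {em.d}, model has d={self.d}"
                )
            if em.n_components != n_comp:
                raise ModelValidityError(
                    "all states must share the same number of mixture components"
                )

    @property
    def K(self) -> int:
        return self.chain.K

    @property
    def n_components(self) -> int:
        return self.emissions[0].n_components

    def copy(self) -> "GaussianHMM":
        return GaussianHMM(
            chain=MarkovChainParams(
                K=self.chain.K,
                A=self.chain.A.copy(),
                pi=self.chain.pi.copy(),
                order=self.chain.order,
            ),
            d=self.d,
            emissions=[
                GaussianMixtureEmission(
                    weights=e.weights.copy(),
                    means=e.means.copy(),
                    covariances=e.covariances.copy(),
                )
                for e in self.emissions
            ],
        )


@dataclass
class ObservationSequence:
    """One subject's recording: an (n, d) array of COP displacements in mm.

    ``channels`` orders the columns (subset of ("ML", "AP")); ``label`` is the
    optional class tag ("healthy" or "pd").
    """

    values: np.ndarray
    sampling_rate_hz: float
    channels: Tuple[str, ...] = ("ML", "AP")
    subject_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.channels = tuple(self.channels)
        if self.values.shape[0] < 1:
            raise SequenceError("sequence must contain at least one sample")
        if self.values.shape[1] != len(self.channels):
            raise SequenceError(
                f"{self.values.shape[1]} columns but {len(self.channels)} "
                f"channel labels {self.channels}"
            )
        if self.sampling_rate_hz <= 0:
            raise SequenceError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise SequenceError(
                f"sequence for subject {self.subject_id!r} contains NaN/inf"
            )
        if self.label is not None and self.label not in ("healthy", "pd"):
            raise SequenceError(f"unknown label {self.label!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate_hz


@dataclass
class PosteriorSet:
    """Forward-backward output: the EM sufficient statistics for one sequence.

    gamma[i, k] is the posterior that sample i came from state k (tau in the
    Gaussian M-step); comp_gamma refines it by mixture component; xi_sum is
    the K x K matrix of expected transition counts summed over time.
    """

    gamma: np.ndarray
    xi_sum: np.ndarray
    comp_gamma: np.ndarray
    loglik: float

    def validate(self) -> None:
        if not np.allclose(self.gamma.sum(axis=1), 1.0, rtol=0, atol=1e-10):
            raise ModelValidityError("gamma rows must sum to 1")
        if not np.allclose(
            self.comp_gamma.sum(axis=2), self.gamma, rtol=0, atol=1e-10
        ):
            raise ModelValidityError("comp_gamma must marginalize to gamma")
        n = self.gamma.shape[0]
        if np.any(self.xi_sum < -1e-12):
            raise ModelValidityError("xi_sum must be nonnegative")
        if n > 1 and abs(self.xi_sum.sum() - (n - 1)) > 1e-8:
            raise ModelValidityError("xi_sum must total n - 1")


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


def _as_values(seq: Union[ObservationSequence, np.ndarray]) -> np.ndarray:
    if isinstance(seq, ObservationSequence):
        return seq.values
    x = np.asarray(seq, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def log_component_densities(
    model: GaussianHMM, seq: Union[ObservationSequence, np.ndarray]
) -> np.ndarray:
    """(n, K, C) array of log [w_kj N(x_i; mu_kj, Sigma_kj)]."""
    X = _as_values(seq)
    n, d = X.shape
    if d != model.d:
        raise DimensionMismatchError(
            f"sequence dimension {d} != model dimension {model.d}"
        )
    if n < 1:
        raise SequenceError("empty sequence")
    if not np.all(np.isfinite(X)):
        raise SequenceError("sequence contains NaN/inf")
    K, C = model.K, model.n_components
    out = np.empty((n, K, C))
    for k, em in enumerate(model.emissions):
        L = em.cholesky_factors()
        for j in range(C):
            dev = X - em.means[j]
            z = solve_triangular(L[j], dev.T, lower=True)
            quad = np.einsum("ij,ij->j", z, z)
            logdet = 2.0 * np.sum(np.log(np.diag(L[j])))
            logw = np.log(em.weights[j]) if em.weights[j] > 0 else -np.inf
            out[:, k, j] = logw - 0.5 * (d * _LOG2PI + logdet + quad)
    return out


def log_emission_matrix(
    model: GaussianHMM, seq: Union[ObservationSequence, np.ndarray]
) -> np.ndarray:
    """(n, K) matrix of log mixture emission densities log p(x_i | state k)."""
    comp = log_component_densities(model, seq)
    return logsumexp(comp, axis=2)


def _discrete_logb(model: DiscreteHMMParams, symbols: np.ndarray) -> np.ndarray:
    symbols = np.asarray(symbols)
    if symbols.size == 0:
        raise SequenceError("empty sequence")
    if symbols.min() < 0 or symbols.max() >= model.M:
        raise SequenceError(
            f"symbols must lie in [0, {model.M}), got range "
            f"[{symbols.min()}, {symbols.max()}]"
        )
    with np.errstate(divide="ignore"):
        return np.log(model.B[:, symbols]).T  # (n, K)


def _model_logb(
    model: Union[GaussianHMM, DiscreteHMMParams],
    seq,
) -> Tuple[MarkovChainParams, np.ndarray]:
    if isinstance(model, GaussianHMM):
        model.chain.require_first_order()
        return model.chain, log_emission_matrix(model, seq)
    model.chain.require_first_order()
    return model.chain, _discrete_logb(model, np.asarray(seq, dtype=int))


def forward_log_likelihood(
    model: Union[GaussianHMM, DiscreteHMMParams],
    seq,
    method: str = "scaled",
) -> float:
    """log p(X | model), summed over all hidden state paths.

    ``method="scaled"`` uses the per-step rescaled forward recursion;
    ``method="log"`` is a pure log-space recursion kept as an internal
    cross-check of the scaling arithmetic.  The two agree to ~1e-10 on any
    input either can handle.
    """
    chain, logb = _model_logb(model, seq)
    if method == "scaled":
        ll = _kernels.forward_ll(chain.pi, chain.A, logb)
        if not np.isfinite(ll):
            raise ModelValidityError("forward recursion lost all probability mass")
        return float(ll)
    if method == "log":
        with np.errstate(divide="ignore"):
            log_pi = np.log(chain.pi)
            log_A = np.log(chain.A)
        la = log_pi + logb[0]
        for t in range(1, logb.shape[0]):
            la = logsumexp(la[:, None] + log_A, axis=0) + logb[t]
        return float(logsumexp(la))
    raise ValueError(f"unknown method {method!r}")


def forward_backward(
    model: GaussianHMM, seq: Union[ObservationSequence, np.ndarray]
) -> PosteriorSet:
    """Smoothed state and component posteriors plus expected transition counts."""
    model.chain.require_first_order()
    comp = log_component_densities(model, seq)
    logb = logsumexp(comp, axis=2)
    gamma, xi_sum, ll = _kernels.forward_backward(
        model.chain.pi, model.chain.A, logb
    )
    if not np.isfinite(ll):
        raise ModelValidityError("forward-backward lost all probability mass")
    # responsibilities within each state, then scaled by the state posterior
    comp_rel = np.exp(comp - logb[:, :, None])
    comp_gamma = gamma[:, :, None] * comp_rel
    return PosteriorSet(
        gamma=gamma, xi_sum=xi_sum, comp_gamma=comp_gamma, loglik=float(ll)
    )


def viterbi(
    model: Union[GaussianHMM, DiscreteHMMParams], seq
) -> Tuple[np.ndarray, float]:
    """Most probable hidden path and its log joint probability log p(X, Z*).

    Ties are broken toward the lower state index.
    """
    chain, logb = _model_logb(model, seq)
    with np.errstate(divide="ignore"):
        log_pi = np.log(chain.pi)
        log_A = np.log(chain.A)
    path, logjoint = _kernels.viterbi_path(log_pi, log_A, logb)
    return path, float(logjoint)


def sample_sequence(
    model: GaussianHMM,
    n: int,
    rng_seed: Union[int, np.random.Generator],
    sampling_rate_hz: float = 100.0,
    channels: Optional[Sequence[str]] = None,
    subject_id: str = "sim",
    label: Optional[str] = None,
) -> Tuple[ObservationSequence, np.ndarray]:
    """Ancestral sampling: draw a hidden path from (pi, A) and observations
    from each visited state's mixture.  Returns (sequence, hidden path)."""
    if n < 1:
        raise SequenceError(f"sequence length must be >= 1, got {n}")
    model.chain.require_first_order()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    K, d, C = model.K, model.d, model.n_components
    states = np.empty(n, dtype=int)
    u = rng.random(n)
    cum_pi = np.cumsum(model.chain.pi)
    cum_A = np.cumsum(model.chain.A, axis=1)
    states[0] = min(int(np.searchsorted(cum_pi, u[0], side="right")), K - 1)
    for t in range(1, n):
        states[t] = min(
            int(np.searchsorted(cum_A[states[t - 1]], u[t], side="right")), K - 1
        )
    chol = [em.cholesky_factors() for em in model.emissions]
    X = np.empty((n, d))
    z = rng.standard_normal((n, d))
    comps = np.empty(n, dtype=int)
    for k in range(K):
        mask = states == k
        if not mask.any():
            continue
        comps[mask] = rng.choice(C, size=mask.sum(), p=model.emissions[k].weights)
    for k in range(K):
        for j in range(C):
            mask = (states == k) & (comps == j)
            if not mask.any():
                continue
            X[mask] = model.emissions[k].means[j] + z[mask] @ chol[k][j].T
    if channels is None:
        channels = ("ML", "AP")[:d] if d <= 2 else tuple(f"ch{i}" for i in range(d))
    seq = ObservationSequence(
        values=X,
        sampling_rate_hz=sampling_rate_hz,
        channels=tuple(channels),
        subject_id=subject_id,
        label=label,
    )
    return seq, states


def brute_force_log_likelihood(
    model: Union[GaussianHMM, DiscreteHMMParams], seq
) -> float:
    """Test oracle: log p(X | model) by explicit summation over all K^n paths.

    Accumulates each path's complete-data log probability
    log [p(z_1) p(x_1|z_1) prod p(z_i|z_{i-1}) p(x_i|z_i)] and combines them
    with logsumexp.  Guarded to K^n <= 1e6.
    """
    chain, logb = _model_logb(model, seq)
    n, K = logb.shape
    if K**n > 10**6:
        raise ValueError(
            f"K^n = {K}^{n} exceeds the 1e6 enumeration guard; "
            "use a smaller instance"
        )
    with np.errstate(divide="ignore"):
        log_pi = np.log(chain.pi)
        log_A = np.log(chain.A)
    path_logps = []
    for path in itertools.product(range(K), repeat=n):
        lp = log_pi[path[0]] + logb[0, path[0]]
        for t in range(1, n):
            lp += log_A[path[t - 1], path[t]] + logb[t, path[t]]
        path_logps.append(lp)
    return float(logsumexp(np.array(path_logps)))


def enumerate_path_posteriors(
    model: Union[GaussianHMM, DiscreteHMMParams], seq
) -> Tuple[np.ndarray, float, Tuple[int, ...], float]:
    """Test oracle companion: exact state posteriors, total log-likelihood,
    and the max-probability path by enumeration.

    Returns (gamma, loglik, best_path, best_log_joint); on log-joint ties the
    lexicographically smallest path is returned.
    """
    chain, logb = _model_logb(model, seq)
    n, K = logb.shape
    if K**n > 10**6:
        raise ValueError("instance too large to enumerate")
    with np.errstate(divide="ignore"):
        log_pi = np.log(chain.pi)
        log_A = np.log(chain.A)
    paths = list(itertools.product(range(K), repeat=n))
    logps = np.empty(len(paths))
    for i, path in enumerate(paths):
        lp = log_pi[path[0]] + logb[0, path[0]]
        for t in range(1, n):
            lp += log_A[path[t - 1], path[t]] + logb[t, path[t]]
        logps[i] = lp
    total = logsumexp(logps)
    w = np.exp(logps - total)
    gamma = np.zeros((n, K))
    for i, path in enumerate(paths):
        for t, s in enumerate(path):
            gamma[t, s] += w[i]
    best = int(np.argmax(logps))  # first occurrence = lexicographically smallest
    return gamma, float(total), paths[best], float(logps[best])
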