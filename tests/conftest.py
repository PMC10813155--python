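"""Shared fixtures and random-model builders."""

import numpy as np
import pytest

from swayhmm import (
    GaussianHMM,
    GaussianMixtureEmission,
    MarkovChainParams,
    ObservationSequence,
)


def random_gaussian_hmm(rng, K=2, d=1, C=1, mean_scale=2.0):
    """A valid random Gaussian-mixture HMM for oracle comparisons."""
    A = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    emissions = []
    for _ in range(K):
        w = rng.dirichlet(np.ones(C))
        means = rng.normal(scale=mean_scale, size=(C, d))
        covs = np.empty((C, d, d))
        for c in range(C):
            M = rng.normal(size=(d, d))
            covs[c] = M @ M.T + 0.3 * np.eye(d)
        emissions.append(
            GaussianMixtureEmission(weights=w, means=means, covariances=covs)
        )
    return GaussianHMM(
        chain=MarkovChainParams(K=K, A=A, pi=pi), d=d, emissions=emissions
    )


def standard_normal_hmm(K=1, d=1):
    """K states all emitting a standard normal; useful degenerate case."""
    emissions = [
        GaussianMixtureEmission(
            weights=np.ones(1),
            means=np.zeros((1, d)),
            covariances=np.eye(d)[None],
        )
        for _ in range(K)
    ]
    return GaussianHMM(
        chain=MarkovChainParams(
            K=K, A=np.full((K, K), 1.0 / K), pi=np.full(K, 1.0 / K)
        ),
        d=d,
        emissions=emissions,
    )


def as_sequence(values, rate=100.0, **kw):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    channels = kw.pop("channels", ("ML", "AP")[: values.shape[1]])
    return ObservationSequence(
        values=values, sampling_rate_hz=rate, channels=channels, **kw
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
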