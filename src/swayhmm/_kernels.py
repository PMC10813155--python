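"""Compiled inner loops for HMM dynamic programming.

The recursions here are sequential in time and dominate the cost of training
on minute-long stabilometric recordings, so they are jitted with numba.
All kernels take a precomputed ``logb`` matrix of per-sample log emission
densities (n x K) and rescale it per time step before exponentiating, which
keeps the scaled recursions finite even when individual densities underflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_ll", "forward_backward", "viterbi_path"]


@njit(cache=True)
def forward_ll(pi, A, logb):
    """Scaled forward recursion; returns log p(X | model)."""
    n, K = logb.shape
    alpha = np.empty(K)
    ll = 0.0
    for t in range(n):
        m = logb[t, 0]
        for k in range(1, K):
            if logb[t, k] > m:
                m = logb[t, k]
        b = np.exp(logb[t] - m)
        if t == 0:
            a = pi * b
        else:
            a = np.dot(alpha, A) * b
        c = a.sum()
        if c <= 0.0 or not np.isfinite(c):
            return -np.inf
        alpha = a / c
        ll += np.log(c) + m
    return ll


@njit(cache=True)
def forward_backward(pi, A, logb):
    """Scaled forward-backward.

    Returns (gamma, xi_sum, loglik): per-sample state posteriors, expected
    transition counts summed over time, and the sequence log-likelihood.
    """
    n, K = logb.shape
    shift = np.empty(n)
    b = np.empty((n, K))
    for t in range(n):
        m = logb[t, 0]
        for k in range(1, K):
            if logb[t, k] > m:
                m = logb[t, k]
        shift[t] = m
        b[t] = np.exp(logb[t] - m)

    alpha = np.empty((n, K))
    ll = 0.0
    a = pi * b[0]
    c = a.sum()
    alpha[0] = a / c
    ll = np.log(c) + shift[0]
    for t in range(1, n):
        a = np.dot(alpha[t - 1], A) * b[t]
        c = a.sum()
        alpha[t] = a / c
        ll += np.log(c) + shift[t]

    beta = np.empty((n, K))
    beta[n - 1] = 1.0 / K
    for t in range(n - 2, -1, -1):
        v = np.dot(A, b[t + 1] * beta[t + 1])
        beta[t] = v / v.sum()

    gamma = alpha * beta
    for t in range(n):
        gamma[t] /= gamma[t].sum()

    xi_sum = np.zeros((K, K))
    for t in range(1, n):
        tot = 0.0
        m = np.empty((K, K))
        for k in range(K):
            for l in range(K):
                v = alpha[t - 1, k] * A[k, l] * b[t, l] * beta[t, l]
                m[k, l] = v
                tot += v
        xi_sum += m / tot
    return gamma, xi_sum, ll


@njit(cache=True)
def viterbi_path(log_pi, log_A, logb):
    """Max-product decoding; ties broken toward the lower state index.

    Returns (path, log joint probability of path and observations).
    """
    n, K = logb.shape
    delta = log_pi + logb[0]
    back = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        new = np.empty(K)
        for l in range(K):
            best = delta[0] + log_A[0, l]
            arg = 0
            for k in range(1, K):
                v = delta[k] + log_A[k, l]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = k
            new[l] = best + logb[t, l]
            back[t, l] = arg
        delta = new
    best = delta[0]
    arg = 0
    for k in range(1, K):
        if delta[k] > best:
            best = delta[k]
            arg = k
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best
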