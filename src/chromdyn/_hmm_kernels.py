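"""Numba kernels for the Bernoulli-emission HMM (scaled forward/backward).

The scaled (linear-space) recursions of Rabiner are used: at each step the
forward vector is normalized by its sum ``c[t]``; the sequence log-likelihood
is ``sum(log c)`` and the backward pass reuses the same scale factors, so
``gamma = alpha * beta`` is already a proper posterior.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(startprob, transmat, frameprob):
    T, K = frameprob.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = startprob * frameprob[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transmat) * frameprob[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return alpha, c


@njit(cache=True)
def backward_scaled(transmat, frameprob, c):
    T, K = frameprob.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transmat @ (frameprob[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def xi_sum(alpha, beta, transmat, frameprob, c):
    """Accumulated expected transition counts sum_t xi_t[i, j]."""
    T, K = frameprob.shape
    out = np.zeros((K, K))
    for t in range(1, T):
        for i in range(K):
            ai = alpha[t - 1, i]
            for j in range(K):
                out[i, j] += ai * transmat[i, j] * frameprob[t, j] \
                    * beta[t, j] / c[t]
    return out


@njit(cache=True)
def viterbi_path(log_start, log_trans, log_frame):
    T, K = log_frame.shape
    delta = log_start + log_frame[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best, arg = -1e300, 0
            for i in range(K):
                v = delta[i] + log_trans[i, j]
                if v > best:
                    best, arg = v, i
            new[j] = best + log_frame[t, j]
            psi[t, j] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
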