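"""Shared dynamic-programming kernels for discrete-state HMMs.

Scaled forward-backward and Viterbi over an arbitrary per-frame
log-emission matrix, numba-compiled.  All functions take the transition
matrix A (K x K), initial distribution pi (K,), and logB (T x K), the
log emission density of each frame under each state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Finite floor standing in for -inf so the DP stays NaN-free.
LOG_FLOOR = -1.0e6


@njit(cache=True)
def forward_backward(A, pi, logB):
    """Scaled forward-backward pass.

    Returns (loglik, gamma, xi_sum) where gamma[t, k] is the posterior
    state probability and xi_sum[j, k] the expected transition counts
    summed over time.
    """
    T, K = logB.shape
    gamma = np.empty((T, K))
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)          # per-frame scaling constants
    bmax = np.empty(T)
    B = np.empty((T, K))
    for t in range(T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        bmax[t] = m
        for k in range(K):
            B[t, k] = np.exp(logB[t, k] - m)

    # forward
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = a * B[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    # backward
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            b = 0.0
            for k in range(K):
                b += A[j, k] * B[t + 1, k] * beta[t + 1, k]
            beta[t, j] = b / c[t + 1]

    # posteriors
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        denom = c[t + 1]
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += (
                    alpha[t, j] * A[j, k] * B[t + 1, k] * beta[t + 1, k] / denom
                )

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t]) + bmax[t]
    return loglik, gamma, xi_sum


@njit(cache=True)
def forward_backward_pooled(A, pi, logB, offsets):
    """Forward-backward over many sequences packed into one logB array.

    ``offsets`` (length n_seq + 1) delimits the sequences.  Returns
    (total loglik, gamma for every frame, pooled xi_sum, summed
    initial-frame posteriors).
    """
    K = logB.shape[1]
    n_seq = offsets.shape[0] - 1
    total = 0.0
    gamma_all = np.empty((logB.shape[0], K))
    xi_sum = np.zeros((K, K))
    gamma0 = np.zeros(K)
    for s in range(n_seq):
        a, b = offsets[s], offsets[s + 1]
        ll, gamma, xi = forward_backward(A, pi, logB[a:b])
        total += ll
        gamma_all[a:b] = gamma
        xi_sum += xi
        for k in range(K):
            gamma0[k] += gamma[0, k]
    return total, gamma_all, xi_sum, gamma0


@njit(cache=True)
def forward_loglik(A, pi, logB):
    """Log-likelihood only (scaled forward pass)."""
    T, K = logB.shape
    alpha = np.empty(K)
    nxt = np.empty(K)
    loglik = 0.0
    m = logB[0, 0]
    for k in range(1, K):
        if logB[0, k] > m:
            m = logB[0, k]
    s = 0.0
    for k in range(K):
        alpha[k] = pi[k] * np.exp(logB[0, k] - m)
        s += alpha[k]
    loglik += np.log(s) + m
    for k in range(K):
        alpha[k] /= s
    for t in range(1, T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        s = 0.0
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[j] * A[j, k]
            nxt[k] = a * np.exp(logB[t, k] - m)
            s += nxt[k]
        loglik += np.log(s) + m
        for k in range(K):
            alpha[k] = nxt[k] / s
    return loglik


@njit(cache=True)
def viterbi(A, pi, logB):
    """Maximum a posteriori state path.

    Ties are broken toward the lowest state index (F < L < R).
    Returns (path, best log joint probability).
    """
    T, K = logB.shape
    logA = np.empty((K, K))
    for j in range(K):
        for k in range(K):
            logA[j, k] = np.log(A[j, k]) if A[j, k] > 0 else LOG_FLOOR
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        lp = np.log(pi[k]) if pi[k] > 0 else LOG_FLOOR
        delta[0, k] = lp + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + logA[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + logA[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + logB[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


@njit(cache=True)
def sample_chain(A, pi, n, u):
    """Ancestral sampling of a state chain given uniforms u (length n)."""
    K = A.shape[0]
    states = np.empty(n, dtype=np.int64)
    r = u[0]
    s = 0
    acc = pi[0]
    while acc < r and s < K - 1:
        s += 1
        acc += pi[s]
    states[0] = s
    for t in range(1, n):
        r = u[t]
        prev = states[t - 1]
        s = 0
        acc = A[prev, 0]
        while acc < r and s < K - 1:
            s += 1
            acc += A[prev, s]
        states[t] = s
    return states
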