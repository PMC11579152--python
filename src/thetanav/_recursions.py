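"""Numba kernels for the HMM forward/backward/Viterbi recursions.

All kernels take the emission log-density matrix ``logB`` of shape (T, M)
and work in the scaled-probability domain: each forward/backward vector is
renormalised at every time step and the log normalisers are accumulated,
so likelihoods of long series never underflow.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(logB, P, delta):
    """Scaled forward pass.

    Returns ``(alpha, loglik)`` where ``alpha[t]`` is the normalised
    forward vector P(state_t | x_1..x_t) and ``loglik`` is
    log P(x_1..x_T).
    """
    T, M = logB.shape
    alpha = np.empty((T, M))
    loglik = 0.0
    a = np.empty(M)
    for t in range(T):
        m = logB[t].max()
        for j in range(M):
            b = np.exp(logB[t, j] - m)
            if t == 0:
                a[j] = delta[j] * b
            else:
                s = 0.0
                for i in range(M):
                    s += alpha[t - 1, i] * P[i, j]
                a[j] = s * b
        c = a.sum()
        for j in range(M):
            alpha[t, j] = a[j] / c
        loglik += np.log(c) + m
    return alpha, loglik


@njit(cache=True)
def backward_scaled(logB, P):
    """Scaled backward pass; each row renormalised to sum 1."""
    T, M = logB.shape
    beta = np.empty((T, M))
    beta[T - 1] = 1.0 / M
    for t in range(T - 2, -1, -1):
        m = logB[t + 1].max()
        s = 0.0
        for i in range(M):
            v = 0.0
            for j in range(M):
                v += P[i, j] * np.exp(logB[t + 1, j] - m) * beta[t + 1, j]
            beta[t, i] = v
            s += v
        for i in range(M):
            beta[t, i] /= s
    return beta


@njit(cache=True)
def e_step(logB, P, delta):
    """One Baum-Welch E-step.

    Returns the smoothed occupancies ``gamma`` (T, M), the summed
    transition responsibilities ``xi_sum`` (M, M) and the data
    log-likelihood under the current parameters.
    """
    T, M = logB.shape
    alpha, loglik = forward_scaled(logB, P, delta)
    beta = backward_scaled(logB, P)
    gamma = alpha * beta
    for t in range(T):
        s = gamma[t].sum()
        for j in range(M):
            gamma[t, j] /= s
    xi_sum = transition_responsibilities(logB, P, alpha, beta)
    return gamma, xi_sum, loglik


@njit(cache=True)
def transition_responsibilities(logB, P, alpha, beta):
    """Summed per-step transition posteriors xi, each step normalised."""
    T, M = logB.shape
    xi_sum = np.zeros((M, M))
    w = np.empty((M, M))
    for t in range(T - 1):
        m = logB[t + 1].max()
        s = 0.0
        for i in range(M):
            for j in range(M):
                v = (alpha[t, i] * P[i, j]
                     * np.exp(logB[t + 1, j] - m) * beta[t + 1, j])
                w[i, j] = v
                s += v
        for i in range(M):
            for j in range(M):
                xi_sum[i, j] += w[i, j] / s
    return xi_sum


@njit(cache=True)
def viterbi_path(logB, logP, logdelta):
    """Jointly most probable state path (argmax over paths).

    Ties are broken toward the lowest state index, matching the
    canonical ascending-mean state order.
    """
    T, M = logB.shape
    score = np.empty((T, M))
    back = np.zeros((T, M), dtype=np.int64)
    for j in range(M):
        score[0, j] = logdelta[j] + logB[0, j]
    for t in range(1, T):
        for j in range(M):
            best = -np.inf
            arg = 0
            for i in range(M):
                v = score[t - 1, i] + logP[i, j]
                if v > best:
                    best = v
                    arg = i
            score[t, j] = best + logB[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(M):
        if score[T - 1, j] > best:
            best = score[T - 1, j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best
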