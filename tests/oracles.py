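"""Independent brute-force implementations used as test oracles.

These deliberately share no code with the package: dense arrays, plain
loops, scalar digamma — the same fixed-point equations coded a second
time so the optimised sparse implementation can be checked against them.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import digamma as _psi


def fixed_point_read_counts(loglik: np.ndarray, alpha0: float,
                            n_iter: int = 10_000) -> np.ndarray:
    """Plain fixed-point iteration of the VB update equations.

    loglik is a dense (N, T) array of log P(R_n | t) with -inf marking
    alleles a read does not hit.  Starts from an equal split of every
    read over its hit alleles and iterates a fixed number of times.
    """
    N, T = loglik.shape
    hit = np.isfinite(loglik)
    r = np.zeros(T)
    for n in range(N):
        ts = np.flatnonzero(hit[n])
        for t in ts:
            r[t] += 1.0 / len(ts)
    for _ in range(n_iter):
        alpha = np.array([alpha0 + r[t] for t in range(T)])
        total = sum(alpha)
        weight = [math.exp(_psi(alpha[t]) - _psi(total)) for t in range(T)]
        r_new = np.zeros(T)
        for n in range(N):
            ts = np.flatnonzero(hit[n])
            num = [math.exp(loglik[n, t] - max(loglik[n, ts])) * weight[t] for t in ts]
            z = sum(num)
            for t, v in zip(ts, num):
                r_new[t] += v / z
        r = r_new
    return r


def fixed_point_elbo(loglik: np.ndarray, alpha0: float,
                     n_iter: int = 10_000) -> float:
    """ELBO at the oracle's fixed point (scalar-loop evaluation)."""
    from scipy.special import gammaln

    N, T = loglik.shape
    hit = np.isfinite(loglik)
    r = fixed_point_read_counts(loglik, alpha0, n_iter)
    alpha = alpha0 + r
    total = alpha.sum()
    dig = [_psi(alpha[t]) - _psi(total) for t in range(T)]
    value = 0.0
    for n in range(N):
        ts = np.flatnonzero(hit[n])
        logw = [loglik[n, t] + dig[t] for t in ts]
        m = max(logw)
        p = [math.exp(v - m) for v in logw]
        z = sum(p)
        for t, pv in zip(ts, p):
            resp = pv / z
            value += resp * (loglik[n, t] + dig[t])
            if resp > 0:
                value -= resp * math.log(resp)
    kl = (gammaln(total) - sum(gammaln(alpha[t]) for t in range(T))
          - gammaln(T * alpha0) + T * gammaln(alpha0)
          + sum((alpha[t] - alpha0) * dig[t] for t in range(T)))
    return value - kl


def random_instance(rng: np.random.Generator, max_reads: int = 8,
                    max_alleles: int = 3) -> np.ndarray:
    """Random small dense log-likelihood instance (-inf for non-hits)."""
    N = int(rng.integers(1, max_reads + 1))
    T = int(rng.integers(1, max_alleles + 1))
    loglik = np.full((N, T), -np.inf)
    for n in range(N):
        n_hits = int(rng.integers(1, T + 1))
        ts = rng.choice(T, size=n_hits, replace=False)
        loglik[n, ts] = -rng.uniform(0.1, 30.0, size=n_hits)
    return loglik


def dense_to_sparse_loglik(loglik: np.ndarray):
    """Convert a dense -inf-padded instance to the package's sparse form."""
    from scipy import sparse

    rows, cols = np.nonzero(np.isfinite(loglik))
    data = loglik[rows, cols]
    return sparse.csr_matrix((data, (rows, cols)), shape=loglik.shape)
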