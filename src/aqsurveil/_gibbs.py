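"""Numba inner loop for the collapsed Gibbs sampler.

The sweep is sequential by construction (each token's conditional depends on
the counts left by the previous draws), so it is compiled rather than
vectorized. The kernel RNG is reseeded deterministically per sweep from
(run seed, sweep index), making trajectories bit-reproducible regardless of
process history.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SEED_MOD = 2**31 - 1


def sweep_seed(rng_seed: int, iteration: int) -> int:
    """Deterministic per-sweep kernel seed derived from (seed, sweep index)."""
    return int((rng_seed * 1_000_003 + iteration * 7_919 + 1) % _SEED_MOD)


@njit(cache=False)
def _seed_kernel(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=False)
def _sweep_kernel(w, doc_of, z, n_dk, n_kw, n_k, alpha, beta):
    K = n_dk.shape[1]
    V = n_kw.shape[1]
    n_tokens = w.shape[0]
    cum = np.empty(K, dtype=np.float64)
    vbeta = V * beta
    for i in range(n_tokens):
        d = doc_of[i]
        t = w[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        n_kw[k_old, t] -= 1
        n_k[k_old] -= 1
        total = 0.0
        for k in range(K):
            total += (n_dk[d, k] + alpha) * (n_kw[k, t] + beta) / (n_k[k] + vbeta)
            cum[k] = total
        u = np.random.random() * total
        k_new = 0
        while k_new < K - 1 and cum[k_new] < u:
            k_new += 1
        z[i] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, t] += 1
        n_k[k_new] += 1


def run_sweep(w, doc_of, z, n_dk, n_kw, n_k, alpha, beta, rng_seed, iteration):
    """One full in-place resampling pass over every token position."""
    _seed_kernel(sweep_seed(rng_seed, iteration))
    _sweep_kernel(w, doc_of, z, n_dk, n_kw, n_k, float(alpha), float(beta))
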