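"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from the mathematical definitions,
sharing no code with the package: the quartic objective as an explicit
4-index contraction, the exact minimum over permutation couplings by
exhaustive enumeration, and a reference entropic solver whose gradient is a
full einsum over the 4-index tensor and whose Sinkhorn runs in the scaling
(u, v) domain with explicit stabilization.
"""

from __future__ import annotations

import itertools

import numpy as np


def gw_cost_loop(A: np.ndarray, B: np.ndarray, G: np.ndarray) -> float:
    """Explicit quadruple loop over (i, j, k, l)."""
    n, m = G.shape
    total = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(m):
                for l in range(m):
                    total += (A[i, j] - B[k, l]) ** 2 * G[i, k] * G[j, l]
    return total


def permutation_minimum(A: np.ndarray, B: np.ndarray) -> float:
    """Exact min of the objective over all n! permutation couplings (1/n)P."""
    n = A.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(n)):
        sigma = list(perm)
        cost = np.mean((A - B[np.ix_(sigma, sigma)]) ** 2)
        best = min(best, cost)
    return best


def _tensor_gradient(A: np.ndarray, B: np.ndarray, G: np.ndarray) -> np.ndarray:
    """d/dG_ik of the objective, via the full 4-index tensor."""
    T = (A[:, None, :, None] - B[None, :, None, :]) ** 2  # index order ikjl
    return 2.0 * np.einsum("ikjl,jl->ik", T, G)


def reference_entropic_gw(
    A: np.ndarray,
    B: np.ndarray,
    epsilon: float,
    G0: np.ndarray,
    n_outer: int = 2000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Reference projected-gradient entropic GW solver.

    The gradient tensor is contracted index-by-index with einsum over the
    full (i, j, k, l) tensor; the Sinkhorn subproblem runs in the scaling
    domain with potentials re-absorbed into the kernel whenever the scalers
    grow large.
    """
    n, m = G0.shape
    p = np.full(n, 1.0 / n)
    q = np.full(m, 1.0 / m)
    G = G0.copy()
    prev = gw_cost_einsum(A, B, G)
    alpha = np.zeros(n)
    beta = np.zeros(m)
    for _ in range(n_outer):
        C = _tensor_gradient(A, B, G)  # full gradient as the subproblem cost
        u = np.ones(n)
        v = np.ones(m)
        K = np.exp(-(C - alpha[:, None] - beta[None, :]) / epsilon)
        for it in range(5000):
            Kv = K @ v
            if np.any(Kv <= 0) or not np.all(np.isfinite(Kv)):
                # absorb the scalers into the potentials and rebuild the kernel
                alpha += epsilon * np.log(np.maximum(u, 1e-300))
                beta += epsilon * np.log(np.maximum(v, 1e-300))
                u = np.ones(n)
                v = np.ones(m)
                K = np.exp(-(C - alpha[:, None] - beta[None, :]) / epsilon)
                continue
            u = p / Kv
            v = q / (K.T @ u)
            if np.max(u) > 1e50 or np.max(v) > 1e50 or it % 10 == 9:
                alpha += epsilon * np.log(np.maximum(u, 1e-300))
                beta += epsilon * np.log(np.maximum(v, 1e-300))
                u = np.ones(n)
                v = np.ones(m)
                K = np.exp(-(C - alpha[:, None] - beta[None, :]) / epsilon)
                G_try = K
                if np.abs(G_try.sum(axis=1) - p).max() < 1e-9:
                    break
        G = u[:, None] * K * v[None, :]
        cur = gw_cost_einsum(A, B, G)
        if abs(cur - prev) < tol:
            break
        prev = cur
    return G


def gw_cost_einsum(A: np.ndarray, B: np.ndarray, G: np.ndarray) -> float:
    """Objective via the explicit 4-index tensor (einsum, not factored)."""
    T = (A[:, None, :, None] - B[None, :, None, :]) ** 2
    return float(np.einsum("ikjl,ik,jl->", T, G, G))
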