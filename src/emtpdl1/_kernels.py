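"""Compiled Euler / Euler-Maruyama steppers for shifted-Hill ODE systems.

The dynamics of node i are

    dX_i/dt = g_i * prod_j Hs(X_j; X0_ji, n_ji, lam_ji) - k_i * X_i

with the shifted Hill multiplier Hs = lam + (1 - lam) / (1 + (X/X0)^n).
Edges are given as parallel index arrays (``src`` regulates ``tgt``);
the sign of regulation is encoded entirely in ``lam`` (lam > 1
activation, lam < 1 inhibition).

Both steppers share the exact arithmetic order, so the stochastic
kernel with zero noise reproduces the deterministic one bit for bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _ipow(x: float, n: int) -> float:
    # n is a small positive integer (Hill coefficient); repeated
    # multiplication avoids the cost of a general pow.
    r = x
    for _ in range(n - 1):
        r *= x
    return r


@njit(cache=True)
def integrate_to_steady(
    x_init,  # (B, N) initial conditions, consumed read-only
    g,  # (B, N)
    k,  # (B, N)
    src,  # (E,)
    tgt,  # (E,)
    lam,  # (B, E)
    hill_n,  # (B, E) int64
    x0,  # (B, E)
    dt: float,
    max_steps: int,
    check_every: int,
    rel_tol: float,
):
    """Euler integration of every row until the relative change of each
    node over a test window of ``check_every`` steps drops below
    ``rel_tol``.  Returns final states and per-row convergence flags."""
    B, N = x_init.shape
    E = src.shape[0]
    out = np.empty((B, N))
    converged = np.zeros(B, dtype=np.bool_)
    x = np.empty(N)
    prev = np.empty(N)
    prod = np.empty(N)
    for b in range(B):
        for i in range(N):
            x[i] = x_init[b, i]
            prev[i] = x[i]
        step = 0
        while step < max_steps:
            for i in range(N):
                prod[i] = 1.0
            for e in range(E):
                l = lam[b, e]
                ratio = x[src[e]] / x0[b, e]
                prod[tgt[e]] *= l + (1.0 - l) / (1.0 + _ipow(ratio, hill_n[b, e]))
            for i in range(N):
                xi = x[i] + dt * (g[b, i] * prod[i] - k[b, i] * x[i]) + 0.0
                x[i] = xi if xi > 0.0 else 0.0
            step += 1
            if step % check_every == 0:
                worst = 0.0
                for i in range(N):
                    scale = abs(x[i])
                    if scale < 1e-12:
                        scale = 1e-12
                    d = abs(x[i] - prev[i]) / scale
                    if d > worst:
                        worst = d
                if worst < rel_tol:
                    converged[b] = True
                    break
                for i in range(N):
                    prev[i] = x[i]
        for i in range(N):
            out[b, i] = x[i]
    return out, converged


@njit(cache=True)
def simulate_sde(
    x_init,  # (T, N) one row per trajectory
    g,  # (N,)
    k,  # (N,)
    src,
    tgt,
    lam,  # (E,)
    hill_n,  # (E,) int64
    x0,  # (E,)
    sigma,  # (N,) additive noise amplitudes
    dt: float,
    n_steps: int,
    stride: int,
    seed: int,
):
    """Euler-Maruyama integration with additive Gaussian noise
    ``sigma_i * sqrt(dt) * N(0,1)`` and reflection at zero.  Every
    ``stride``-th state (plus the initial one) is recorded."""
    np.random.seed(seed)
    T, N = x_init.shape
    E = src.shape[0]
    n_rec = n_steps // stride + 1
    out = np.empty((T, n_rec, N))
    sqdt = np.sqrt(dt)
    x = np.empty(N)
    prod = np.empty(N)
    for t in range(T):
        for i in range(N):
            x[i] = x_init[t, i]
            out[t, 0, i] = x[i]
        rec = 1
        for step in range(1, n_steps + 1):
            for i in range(N):
                prod[i] = 1.0
            for e in range(E):
                l = lam[e]
                ratio = x[src[e]] / x0[e]
                prod[tgt[e]] *= l + (1.0 - l) / (1.0 + _ipow(ratio, hill_n[e]))
            for i in range(N):
                noise = sigma[i] * sqdt * np.random.normal(0.0, 1.0) if sigma[i] > 0.0 else 0.0
                xi = x[i] + dt * (g[i] * prod[i] - k[i] * x[i]) + noise
                x[i] = xi if xi > 0.0 else 0.0
            if step % stride == 0:
                for i in range(N):
                    out[t, rec, i] = x[i]
                rec += 1
    return out


@njit(cache=True)
def hill_product(x, g, k, src, tgt, lam, hill_n, x0):
    """Right-hand side g_i * prod Hs - k_i * X_i for one state vector."""
    N = x.shape[0]
    E = src.shape[0]
    prod = np.ones(N)
    for e in range(E):
        l = lam[e]
        ratio = x[src[e]] / x0[e]
        prod[tgt[e]] *= l + (1.0 - l) / (1.0 + _ipow(ratio, hill_n[e]))
    rhs = np.empty(N)
    for i in range(N):
        rhs[i] = g[i] * prod[i] - k[i] * x[i]
    return rhs
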