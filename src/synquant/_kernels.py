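"""Numba-compiled forward-algorithm cores for the occupancy hidden chain.

Both kernels take a precomputed density table ``dens[m, k] = P[A_m | k]``
(or an all-ones table to obtain pure release-count propagation), the
per-spike release probabilities ``u``, per-interval restock probabilities
``g`` and a Pascal triangle of binomial coefficients.  State vectors are
renormalized after every step with the log-scale accumulated, so results
stay finite for trains of thousands of spikes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_loglik", "forward_loglik_uncorrelated", "pascal_table"]


def pascal_table(n: int) -> np.ndarray:
    """Binomial coefficients C(i, j) for i, j <= n as float64."""
    tab = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        tab[i, 0] = 1.0
        for j in range(1, i + 1):
            tab[i, j] = tab[i - 1, j - 1] + tab[i - 1, j]
    return tab


@njit(cache=True)
def _release_step(v, dens_m, um, n, pascal, w, upow, qpow):
    """w[z] = sum_{y >= z} v[y] C(y, y-z) u^(y-z) (1-u)^z dens[y-z]."""
    upow[0] = 1.0
    qpow[0] = 1.0
    for i in range(1, n + 1):
        upow[i] = upow[i - 1] * um
        qpow[i] = qpow[i - 1] * (1.0 - um)
    for z in range(n + 1):
        w[z] = 0.0
    for y in range(n + 1):
        vy = v[y]
        if vy == 0.0:
            continue
        for k in range(y + 1):
            w[y - k] += vy * pascal[y, k] * upow[k] * qpow[y - k] * dens_m[k]


@njit(cache=True)
def _restock_step(w, gm, n, pascal, v, gpow, hpow):
    """v[y'] = sum_{z <= y'} w[z] C(n-z, y'-z) g^(y'-z) (1-g)^(n-y')."""
    gpow[0] = 1.0
    hpow[0] = 1.0
    for i in range(1, n + 1):
        gpow[i] = gpow[i - 1] * gm
        hpow[i] = hpow[i - 1] * (1.0 - gm)
    for y in range(n + 1):
        v[y] = 0.0
    for z in range(n + 1):
        wz = w[z]
        if wz == 0.0:
            continue
        e = n - z
        for y2 in range(z, n + 1):
            v[y2] += wz * pascal[e, y2 - z] * gpow[y2 - z] * hpow[n - y2]


@njit(cache=True)
def forward_loglik(dens, u, g, n, pascal):
    """Log of <L_M| Q_{M-1} ... Q_1 |R_0> with |R_0> = delta_{y,n}."""
    M = dens.shape[0]
    v = np.zeros(n + 1)
    v[n] = 1.0
    w = np.empty(n + 1)
    upow = np.empty(n + 1)
    qpow = np.empty(n + 1)
    gpow = np.empty(n + 1)
    hpow = np.empty(n + 1)
    logscale = 0.0
    for m in range(M):
        _release_step(v, dens[m], u[m], n, pascal, w, upow, qpow)
        s = 0.0
        for z in range(n + 1):
            s += w[z]
        if not (s > 0.0) or not np.isfinite(s):
            return -np.inf
        if m == M - 1:
            return logscale + np.log(s)
        logscale += np.log(s)
        for z in range(n + 1):
            w[z] /= s
        _restock_step(w, g[m], n, pascal, v, gpow, hpow)
        s2 = 0.0
        for y in range(n + 1):
            s2 += v[y]
        for y in range(n + 1):
            v[y] /= s2
        logscale += np.log(s2)
    return logscale


@njit(cache=True)
def forward_loglik_uncorrelated(dens, u, g, n, pascal):
    """Factorized log-likelihood: sum_m log sum_k P[A_m|k] P(k_m = k).

    The marginal P(k_m) is the exact release-count distribution obtained by
    propagating the occupancy distribution with the amplitude-independent
    kernel (spike times are conditioned on, observed amplitudes are not).
    """
    M = dens.shape[0]
    v = np.zeros(n + 1)
    v[n] = 1.0
    w = np.empty(n + 1)
    pk = np.empty(n + 1)
    upow = np.empty(n + 1)
    qpow = np.empty(n + 1)
    gpow = np.empty(n + 1)
    hpow = np.empty(n + 1)
    total = 0.0
    for m in range(M):
        um = u[m]
        upow[0] = 1.0
        qpow[0] = 1.0
        for i in range(1, n + 1):
            upow[i] = upow[i - 1] * um
            qpow[i] = qpow[i - 1] * (1.0 - um)
        for z in range(n + 1):
            w[z] = 0.0
            pk[z] = 0.0
        for y in range(n + 1):
            vy = v[y]
            if vy == 0.0:
                continue
            for k in range(y + 1):
                term = vy * pascal[y, k] * upow[k] * qpow[y - k]
                pk[k] += term
                w[y - k] += term
        sm = 0.0
        for k in range(n + 1):
            sm += dens[m, k] * pk[k]
        if not (sm > 0.0) or not np.isfinite(sm):
            return -np.inf
        total += np.log(sm)
        if m < M - 1:
            sw = 0.0
            for z in range(n + 1):
                sw += w[z]
            for z in range(n + 1):
                w[z] /= sw
            _restock_step(w, g[m], n, pascal, v, gpow, hpow)
    return total
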