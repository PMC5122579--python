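"""Observation model: density of a measured EPSP amplitude given k releases.

The sum of ``k`` i.i.d. gamma quantal amplitudes (mean ``mu_a``, s.d.
``sigma_a``) is gamma with shape ``beta = k mu_a^2 / sigma_a^2`` and rate
``lam = mu_a / sigma_a^2``; the observed amplitude adds independent Gaussian
background noise of s.d. ``sigma_b``.  For ``k = 0`` the density is the pure
Gaussian; for ``k >= 1`` it is the gamma-Gaussian convolution

    P[A|k] = int_0^inf dy  Gamma(y; beta, lam) * N(A - y; 0, sigma_b^2).

The integrand is log-concave, so it is unimodal with an analytically known
stationary point.  The integral is evaluated in log-space by three-panel
Gauss-Legendre quadrature on a window found by expanding outward from that
peak until the integrand has dropped far below it, with a square-root
substitution on the lowest panel to absorb the ``y^(beta-1)`` endpoint
behaviour when the window touches zero.  Since ``mu_a > sigma_a`` implies
``beta > 1`` for every ``k >= 1``, the integrand is always bounded.
Correctness is pinned in the tests against adaptive quadrature and
Monte-Carlo oracles, not against a particular rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .dynamics import ModelParams

__all__ = [
    "QuantalShape",
    "quantal_shape",
    "amplitude_log_density",
    "amplitude_density_table",
]

_NODES_PER_PANEL = 48
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_NODES_PER_PANEL)
# nodes/weights mapped to [0, 1]
_GL01_X = 0.5 * (_GL_X + 1.0)
_GL01_W = 0.5 * _GL_W


@dataclass(frozen=True)
class QuantalShape:
    """Gamma shape/rate of the release-dependent amplitude component."""

    k: int
    beta: float
    lam: float


def quantal_shape(k: int, params: ModelParams) -> QuantalShape:
    """Shape ``beta = k mu_a^2/sigma_a^2`` and rate ``lam = mu_a/sigma_a^2``.

    For ``k = 0`` the component is degenerate at zero, flagged by
    ``beta == 0``.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return QuantalShape(k=0, beta=0.0, lam=params.mu_a / params.sigma_a**2)
    beta = k * params.mu_a**2 / params.sigma_a**2
    lam = params.mu_a / params.sigma_a**2
    return QuantalShape(k=int(k), beta=beta, lam=lam)


def _gauss_log_density(A: np.ndarray, sigma_b: float) -> np.ndarray:
    return -0.5 * (A / sigma_b) ** 2 - 0.5 * np.log(2.0 * np.pi) - np.log(sigma_b)


def _log_integrand(y, A, beta: float, lam: float, sigma_b: float, log_norm: float):
    with np.errstate(divide="ignore", invalid="ignore"):
        logy = np.where(y > 0.0, np.log(np.maximum(y, 1e-300)), -np.inf)
    return log_norm + (beta - 1.0) * logy - lam * y + _gauss_log_density(A - y, sigma_b)


def _conv_log_density(A: np.ndarray, beta: float, lam: float, sigma_b: float) -> np.ndarray:
    """Vectorized log of the gamma(beta, lam) x N(0, sigma_b^2) convolution."""
    A = np.atleast_1d(np.asarray(A, dtype=float))
    log_norm = beta * np.log(lam) - gammaln(beta)
    sb2 = sigma_b * sigma_b
    bm1 = max(beta - 1.0, 0.0)

    # The log-integrand is concave, so it is unimodal with its stationary
    # point at the positive root of (beta-1)/y - lam - (y-A)/sb^2 = 0.
    half = 0.5 * (A - lam * sb2)
    ystar = np.maximum(half + np.sqrt(half**2 + bm1 * sb2), 1e-300)
    fpeak = _log_integrand(ystar, A, beta, lam, sigma_b, log_norm)
    with np.errstate(divide="ignore", over="ignore"):
        width = 1.0 / np.sqrt(bm1 / ystar**2 + 1.0 / sb2)
    # keep a usable seed scale even when ystar underflows (deep left tail)
    seed = np.maximum(6.0 * width, 1e-6 * sigma_b)

    # expand the integration window geometrically until the integrand has
    # dropped ~55 nats below its peak on each side (or hit y = 0)
    drop = 55.0
    d_hi = seed.copy()
    for _ in range(90):
        f = _log_integrand(ystar + d_hi, A, beta, lam, sigma_b, log_norm)
        need = f > fpeak - drop
        if not np.any(need):
            break
        d_hi = np.where(need, d_hi * 1.6, d_hi)
    d_lo = seed.copy()
    for _ in range(90):
        yl = ystar - d_lo
        f = _log_integrand(np.maximum(yl, 1e-300), A, beta, lam, sigma_b, log_norm)
        need = (yl > 0.0) & (f > fpeak - drop)
        if not np.any(need):
            break
        d_lo = np.where(need, d_lo * 1.6, d_lo)

    # three Gauss-Legendre panels: peak +/- 6 widths, flanked by the tail
    # panels; the lowest panel uses y = b0 + span t^2 to absorb the
    # y^(beta-1) endpoint behaviour when the window touches zero
    b0 = np.maximum(ystar - d_lo, 0.0)
    b3 = ystar + d_hi
    b1 = np.clip(ystar - 6.0 * width, b0, b3)
    b2 = np.clip(ystar + 6.0 * width, b0, b3)
    t = _GL01_X[None, :]
    w01 = _GL01_W[None, :]
    ys = []
    jacs = []
    with np.errstate(divide="ignore"):
        span = (b1 - b0)[:, None]
        ys.append(b0[:, None] + span * t**2)
        jacs.append(np.log(2.0 * span * t * w01))
        for a, b in ((b1, b2), (b2, b3)):
            span = (b - a)[:, None]
            ys.append(a[:, None] + span * t)
            jacs.append(np.log(span * w01))
    y = np.concatenate(ys, axis=1)
    logjac = np.concatenate(jacs, axis=1)

    log_integrand = _log_integrand(y, A[:, None], beta, lam, sigma_b, log_norm) + logjac
    m = np.max(log_integrand, axis=1)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = m_safe + np.log(np.sum(np.exp(log_integrand - m_safe[:, None]), axis=1))
    return np.where(np.isfinite(m), out, -np.inf)


def amplitude_log_density(A, k: int, params: ModelParams):
    """Log density (natural scale is 1/mV) of amplitude ``A`` given ``k``.

    Accepts a scalar or array ``A``; returns matching shape.
    """
    A_arr = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A_arr)):
        raise ValueError("amplitude must be finite")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        out = _gauss_log_density(A_arr, params.sigma_b)
    else:
        shape = quantal_shape(k, params)
        out = _conv_log_density(A_arr.ravel(), shape.beta, shape.lam, params.sigma_b)
        out = out.reshape(A_arr.shape)
    if A_arr.ndim == 0:
        return float(out)
    return out


def amplitude_density_table(amps, k_max: int, params: ModelParams) -> np.ndarray:
    """Densities ``P[A_i | k]`` as a ``len(amps) x (k_max + 1)`` matrix.

    Column ``k`` holds the natural-scale density of each amplitude given
    ``k`` released vesicles; column 0 is the pure-noise Gaussian.
    """
    amps = np.asarray(amps, dtype=float)
    if amps.ndim != 1:
        raise ValueError("amps must be a 1-D sequence")
    if not np.all(np.isfinite(amps)):
        raise ValueError("amplitudes must be finite")
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    table = np.empty((amps.size, k_max + 1))
    table[:, 0] = np.exp(_gauss_log_density(amps, params.sigma_b))
    lam = params.mu_a / params.sigma_a**2
    for k in range(1, k_max + 1):
        beta = k * params.mu_a**2 / params.sigma_a**2
        table[:, k] = np.exp(_conv_log_density(amps, beta, lam, params.sigma_b))
    if not np.all(np.isfinite(table)):
        raise FloatingPointError("non-finite amplitude density encountered")
    return table
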