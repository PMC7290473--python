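"""Tail probability of a weighted sum of 1-df chi-square variables.

The HEIDI statistic Q = sum_i z_i^2 for a correlated Gaussian vector z is
distributed, under the null, as sum_k lambda_k * chi2_1 where lambda_k are
the eigenvalues of the correlation matrix of z.  The survival function is
evaluated by numerical inversion of the characteristic function (Imhof's
method):

    P(Q > q) = 1/2 + (1/pi) * I,    I = int_0^inf sin(theta(u)) / (u rho(u)) du
    theta(u) = (1/2) sum_k arctan(lambda_k u) - q u / 2
    rho(u)   = prod_k (1 + lambda_k^2 u^2)^(1/4)

The integrand oscillates with asymptotic period 4*pi/q while its envelope
decays only polynomially, so adaptive quadrature on the whole half-line is
unreliable.  Instead the integral is split into one chunk per oscillation
period and each chunk is evaluated by fixed-order Gauss-Legendre (the
integrand is smooth within a period); the alternating chunk series is
truncated once the envelope bound drops below 1e-8, which bounds the
truncation error by the same amount.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["chi2comb_sf"]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)
_TRUNCATION_TOL = 1e-8
_MAX_CHUNKS = 40_000


def _integrand(u: np.ndarray, q: float, lam: np.ndarray) -> np.ndarray:
    theta = 0.5 * np.sum(np.arctan(lam[:, None] * u), axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.sum(np.log1p((lam[:, None] * u) ** 2), axis=0)
    return np.sin(theta) * np.exp(-log_rho) / u


def _envelope(u: np.ndarray, lam: np.ndarray) -> np.ndarray:
    log_rho = 0.25 * np.sum(np.log1p((lam[:, None] * u) ** 2), axis=0)
    return np.exp(-log_rho) / u


def chi2comb_sf(q: float, weights) -> float:
    """P(sum_k w_k X_k > q) for independent X_k ~ chi2(1 df), w_k >= 0.

    Parameters
    ----------
    q : float
        Evaluation point (the observed statistic).
    weights : array-like
        Non-negative weights; tiny negative eigenvalues from numerical
        round-off are clipped to zero.

    Returns
    -------
    float
        Upper-tail probability, clipped to [0, 1]; absolute accuracy
        around 1e-8.
    """
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0 or q <= 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1))
    if np.allclose(lam, lam[0], rtol=1e-10):
        return float(stats.chi2.sf(q / lam[0], df=lam.size))

    period = 4.0 * np.pi / max(q, 1.0)
    # truncation point: one chunk's magnitude is at most envelope * period
    us = np.logspace(-2, 10, 500)
    bound = _envelope(us, lam) * period
    below = np.flatnonzero(bound < _TRUNCATION_TOL)
    u_max = us[below[0]] if below.size else us[-1]
    n_chunks = min(int(np.ceil(u_max / period)), _MAX_CHUNKS)

    edges = period * np.arange(n_chunks + 1)
    half = 0.5 * period
    centers = edges[:-1] + half
    nodes = (centers[:, None] + half * _GL_NODES[None, :]).ravel()
    values = _integrand(nodes, q, lam).reshape(n_chunks, -1)
    integral = float(half * np.sum(values @ _GL_WEIGHTS))

    p = 0.5 + integral / np.pi
    return float(min(max(p, 0.0), 1.0))
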