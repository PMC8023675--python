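"""Gamma-Poisson (negative binomial) log-pmf, deviance and variance function.

The distribution is parameterized by its mean ``mu`` and an overdispersion
``theta >= 0`` such that ``Var(Y) = mu + theta * mu**2``.  ``theta`` is the
reciprocal of the classical negative-binomial "size"; ``theta = 0`` is the
Poisson distribution, handled by a dedicated branch rather than a numerical
limit.  All likelihood work happens in log space.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "gp_logpmf",
    "gp_unit_deviance",
    "gp_variance",
    "gene_loglik",
]

#: mean used for the saturated model when y == 0 (analytic limit form)
SATURATED_EPS = 1e-10


#: overdispersions below this are routed to the Poisson branch: the NB pmf
#: differs from Poisson by less than float precision there, and 1/theta
#: would lose all accuracy in the gamma-function terms
THETA_TINY = 1e-16


def _validate(y, mu, theta):
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(y != np.floor(y)):
        raise ValueError("counts must be integers")
    if np.any(theta < 0):
        raise ValueError("theta must be non-negative")
    if np.any(mu < 0) or np.any((mu == 0) & (y > 0)):
        raise ValueError("mu must be positive (mu == 0 allowed only with y == 0)")
    return y, mu, theta


def gp_variance(mu, theta):
    """Variance function ``mu + theta * mu**2``."""
    mu = np.asarray(mu, dtype=float)
    return mu * (1.0 + np.asarray(theta, dtype=float) * mu)


def gp_logpmf(y, mu, theta):
    """Log probability mass of the Gamma-Poisson distribution.

    Parameters
    ----------
    y : int or array-like
        Observed counts, non-negative integers.
    mu : float or array-like
        Expected counts, positive (``mu == 0`` is allowed where ``y == 0``
        and contributes log-probability 0).
    theta : float or array-like
        Overdispersion, non-negative.  ``theta == 0`` evaluates the Poisson
        log-pmf exactly.

    Returns
    -------
    float or ndarray
        ``log P(Y = y)``; finite for all valid inputs.
    """
    scalar = np.isscalar(y) and np.isscalar(mu) and np.isscalar(theta)
    y, mu, theta = _validate(y, mu, theta)
    y, mu, theta = np.broadcast_arrays(y, mu, theta)
    out = np.empty(y.shape, dtype=float)

    degenerate = mu == 0  # only with y == 0: P(Y=0) = 1
    pois = (theta < THETA_TINY) & ~degenerate
    nb = (theta >= THETA_TINY) & ~degenerate

    out[degenerate] = 0.0
    if np.any(pois):
        yp, mp = y[pois], mu[pois]
        out[pois] = yp * np.log(mp) - mp - gammaln(yp + 1.0)
    if np.any(nb):
        yn, mn, tn = y[nb], mu[nb], theta[nb]
        r = 1.0 / tn
        tm = tn * mn
        out[nb] = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1.0)
            + yn * (np.log(tm) - np.log1p(tm))
            - r * np.log1p(tm)
        )
    return float(out[()]) if scalar else out


def gp_unit_deviance(y, mu, theta):
    """Unit deviance ``2*[l(y; mu=y) - l(y; mu)]`` of the Gamma-Poisson model.

    The saturated-model mean is ``max(y, eps)``; for ``y == 0`` the analytic
    limit is used so the ``0*log(0)`` terms vanish exactly:
    ``2*mu`` for the Poisson branch and ``(2/theta)*log1p(theta*mu)``
    otherwise.  Always non-negative.
    """
    scalar = np.isscalar(y) and np.isscalar(mu) and np.isscalar(theta)
    y, mu, theta = _validate(y, mu, theta)
    y, mu, theta = np.broadcast_arrays(y, mu, theta)
    out = np.empty(y.shape, dtype=float)

    zero = y == 0
    pois0 = zero & (theta < THETA_TINY)
    nb0 = zero & (theta >= THETA_TINY)
    out[pois0] = 2.0 * mu[pois0]
    if np.any(nb0):
        out[nb0] = (2.0 / theta[nb0]) * np.log1p(theta[nb0] * mu[nb0])

    pos = ~zero
    if np.any(pos):
        yp, mp, tp = y[pos], mu[pos], theta[pos]
        pois = tp < THETA_TINY
        nb = ~pois
        dev = np.empty(yp.shape, dtype=float)
        if np.any(pois):
            dev[pois] = 2.0 * (
                yp[pois] * np.log(yp[pois] / mp[pois]) - (yp[pois] - mp[pois])
            )
        if np.any(nb):
            yn, mn, tn = yp[nb], mp[nb], tp[nb]
            # 2*[y log(y/mu) - (y + 1/theta) log((1+theta y)/(1+theta mu))]
            dev[nb] = 2.0 * (
                yn * np.log(yn / mn)
                - (yn + 1.0 / tn) * (np.log1p(tn * yn) - np.log1p(tn * mn))
            )
        out[pos] = dev
    np.maximum(out, 0.0, out=out)  # guard rounding at the saturated point
    return float(out[()]) if scalar else out


def gene_loglik(counts, mus, theta):
    """Sum of ``gp_logpmf`` over one gene's observations.

    ``counts`` and ``mus`` must have equal length; the empty sum is 0.
    """
    counts = np.asarray(counts, dtype=float)
    mus = np.asarray(mus, dtype=float)
    if counts.shape != mus.shape:
        raise ValueError(
            f"length mismatch: {counts.shape} counts vs {mus.shape} means"
        )
    if counts.size == 0:
        return 0.0
    return float(np.sum(gp_logpmf(counts, mus, theta)))
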