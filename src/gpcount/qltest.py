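"""Quasi-likelihood F-test with empirical-Bayes shrinkage.

Both the full and the reduced model are fitted at the trended dispersion;
the per-gene quasi-dispersion sigma^2 = deviance / df_residual then absorbs
residual gene-level variability.  Gene-wise quasi-dispersions are squeezed
toward a common location with a prior degree of freedom estimated by
moment-matching log sigma^2 to a scaled-F distribution (trigamma
inversion), and the deviance drop per constraint over the shrunken
quasi-dispersion is referred to an F distribution with augmented
denominator degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

__all__ = [
    "QLShrinkage",
    "quasi_dispersion",
    "trigamma_inverse",
    "estimate_prior",
    "shrink_quasi_dispersions",
    "ql_f_test",
    "bh_adjust",
    "contrast_lfc",
]

SIGMA2_FLOOR = 1e-8


def quasi_dispersion(deviance, df_residual) -> np.ndarray:
    """Per-gene quasi-dispersion: deviance / residual df, floored at 1e-8."""
    deviance = np.asarray(deviance, dtype=float)
    df = np.asarray(df_residual, dtype=float)
    if np.any(df < 1):
        raise ValueError("quasi-dispersion requires df_residual >= 1")
    return np.maximum(deviance / df, SIGMA2_FLOOR)


def _trigamma(x):
    return polygamma(1, x)


def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration.

    Uses the asymptotic start ``x ~ 0.5 + 1/y`` and the monotone update on
    1/trigamma; converges in a handful of steps for all y > 0.
    """
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class QLShrinkage:
    sigma2_gene: np.ndarray
    sigma2_trend: float
    df_prior: float  # may be inf
    df_residual: np.ndarray
    sigma2_shrunk: np.ndarray


def estimate_prior(sigma2_gene, df_residual) -> tuple[float, float]:
    """Moment-match gene-wise quasi-dispersions to a scaled F prior.

    Under the prior, sigma2_g ~ sigma2_trend * F(df_residual, df_prior), so
    log sigma2 has variance trigamma(df_residual/2) + trigamma(df_prior/2).
    df_prior is solved from the excess empirical variance of log sigma2 by
    trigamma inversion; at-or-below the theoretical minimum (or with fewer
    than 10 genes) the prior is infinitely concentrated (df_prior = inf).

    Returns ``(sigma2_trend, df_prior)``.
    """
    sigma2 = np.asarray(sigma2_gene, dtype=float)
    df = np.broadcast_to(np.asarray(df_residual, dtype=float), sigma2.shape)
    keep = np.isfinite(sigma2) & (sigma2 > 0) & (df >= 1)
    sigma2, df = sigma2[keep], df[keep]
    if sigma2.size < 10:
        warnings.warn(
            "fewer than 10 genes for prior estimation; using an infinite prior df",
            stacklevel=2,
        )
        loc = float(np.median(sigma2)) if sigma2.size else 1.0
        return loc, np.inf

    z = np.log(sigma2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(_trigamma(df / 2.0)))
    if e_var <= 0:
        # no detectable gene-to-gene spread beyond chi-square noise: take the
        # geometric mean of the observed values as the (degenerate) location
        return float(np.exp(np.mean(z))), np.inf
    df_prior = 2.0 * trigamma_inverse(e_var)
    sigma2_trend = float(np.exp(e_mean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    return sigma2_trend, df_prior


def shrink_quasi_dispersions(sigma2_gene, df_residual) -> QLShrinkage:
    """Squeeze gene-wise quasi-dispersions toward the estimated prior location."""
    sigma2 = np.asarray(sigma2_gene, dtype=float)
    df = np.broadcast_to(np.asarray(df_residual, dtype=float), sigma2.shape).astype(float)
    trend, d0 = estimate_prior(sigma2, df)
    if np.isinf(d0):
        shrunk = np.full(sigma2.shape, trend)
    else:
        shrunk = (d0 * trend + df * sigma2) / (d0 + df)
    return QLShrinkage(
        sigma2_gene=sigma2, sigma2_trend=trend, df_prior=d0,
        df_residual=df, sigma2_shrunk=shrunk,
    )


def ql_f_test(deviance_full, deviance_reduced, df1, df_residual,
              sigma2_shrunk, df_prior) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quasi-likelihood F statistics and p-values for nested model pairs.

    ``F = [(dev_reduced - dev_full)/df1] / sigma2_shrunk`` floored at 0;
    p-values are the upper tail of ``F(df1, df_prior + df_residual)``, or
    the chi-square/df1 limit when the prior df is infinite.  A deviance
    difference below -1e-8 indicates a fitting bug and raises; smaller
    negatives are clipped to 0.

    Returns ``(F, df2, p)`` as arrays.
    """
    dev_f = np.asarray(deviance_full, dtype=float)
    dev_r = np.asarray(deviance_reduced, dtype=float)
    df1 = float(df1)
    if df1 < 1:
        raise ValueError("df1 = p_full - p_reduced must be >= 1")
    diff = dev_r - dev_f
    if np.any(diff < -1e-8):
        bad = int(np.argmin(diff))
        raise ValueError(
            f"reduced-model deviance below full-model deviance by {-diff[bad]:.3g} "
            f"(gene index {bad}); the fits are inconsistent"
        )
    diff = np.maximum(diff, 0.0)
    F = diff / df1 / np.asarray(sigma2_shrunk, dtype=float)
    df_res = np.broadcast_to(np.asarray(df_residual, dtype=float), F.shape)
    if np.isinf(df_prior):
        df2 = np.full(F.shape, np.inf)
        p = stats.chi2.sf(F * df1, df1)
    else:
        df2 = df_prior + df_res
        p = stats.f.sf(F, df1, df2)
    return F, df2, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values propagate and do not count toward the number of tests;
    ties are handled stably by the monotone cumulative minimum.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def contrast_lfc(beta, contrast) -> float:
    """Log2 fold change of a linear contrast of the coefficients."""
    beta = np.asarray(beta, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if beta.shape != contrast.shape:
        raise ValueError(
            f"contrast length {contrast.size} does not match {beta.size} coefficients"
        )
    return float(contrast @ beta / np.log(2.0))
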