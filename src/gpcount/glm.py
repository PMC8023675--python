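"""Per-gene Gamma-Poisson GLM fitting: log mu = X beta + offset.

Coefficients are estimated by deviance-minimizing iteratively reweighted
least squares (Fisher scoring) with step-halving, a linear-predictor clamp
against overflow, and a Poisson (theta = 0) fast path.  Each gene is fitted
independently, so fitting streams over gene chunks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._distribution import gp_unit_deviance
from .design import DesignSpec

__all__ = ["GeneFit", "initialize_beta", "fit_beta", "fit_all_genes"]

#: clamp on the linear predictor eta + offset (log mu)
ETA_CLAMP = 30.0
#: divergence guard on the coefficient vector
BETA_CLAMP = 50.0
MAX_ITER = 100
MAX_HALVINGS = 20
DEV_RTOL = 1e-8


@dataclass
class GeneFit:
    """Result of one gene's GLM fit at a fixed overdispersion."""

    beta: np.ndarray
    mu: np.ndarray  # fitted means, s_c * exp((X beta)_c)
    theta_used: float
    deviance: float
    df_residual: int
    iterations: int
    converged: bool
    all_zero: bool = False
    clamped: bool = False
    dev_trace: list = field(default_factory=list, repr=False)

    @property
    def mean_expression(self) -> float:
        return float(np.mean(self.mu))


def _as_design(X) -> DesignSpec:
    return X if isinstance(X, DesignSpec) else DesignSpec(np.asarray(X, dtype=float))


def _wls(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares via orthogonal decomposition (lstsq/SVD);
    exact for full-rank X, deterministic."""
    sw = np.sqrt(w)
    beta, *_ = linalg.lstsq(X * sw[:, None], z * sw, lapack_driver="gelsd")
    return beta


def initialize_beta(y, X, offsets) -> np.ndarray:
    """Starting coefficients: OLS of ``X beta ~ log((y + 0.5)/s)``.

    Finite for all-zero genes (the response rows become ``log 0.5``).
    """
    design = _as_design(X)
    y = np.asarray(y, dtype=float)
    z = np.log(y + 0.5) - np.asarray(offsets, dtype=float)
    beta, *_ = linalg.lstsq(design.X, z, lapack_driver="gelsd")
    return beta


def _mu_from_beta(X, beta, offsets):
    lp = np.clip(X @ beta + offsets, -ETA_CLAMP, ETA_CLAMP)
    return np.exp(lp), lp


def fit_beta(y, X, offsets=None, theta: float = 0.0, init=None) -> GeneFit:
    """Fit beta for one gene at fixed overdispersion by IRLS.

    Parameters
    ----------
    y : array of non-negative integer counts, one per cell.
    X : DesignSpec or array (cells x p), full rank.
    offsets : log size factors (defaults to 0).
    theta : overdispersion held fixed during the fit; 0 uses the Poisson
        working weights exactly.
    init : optional starting beta; defaults to :func:`initialize_beta`.

    Each iteration solves the weighted least-squares normal equations with
    working weights ``w = mu/(1 + theta*mu)`` and working response
    ``z = eta + (y - mu)/mu``; a step that would increase the deviance is
    halved (up to 20 times).  Convergence is a relative deviance change
    below 1e-8; the ``converged`` flag additionally requires the score
    ``X^T [(y-mu)/(1+theta*mu)]`` to vanish to 1e-6*(1+|sum y|).
    """
    design = _as_design(X)
    Xm = design.X
    n, p = Xm.shape
    y = np.asarray(y, dtype=float)
    if y.shape[0] != n:
        raise ValueError(f"{y.shape[0]} counts for a design with {n} rows")
    if np.any(~np.isfinite(y)):
        raise ValueError("counts contain non-finite values")
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    theta = float(theta)

    if np.all(y == 0):
        # boundary fit: push log mu to the clamp floor
        beta, *_ = linalg.lstsq(Xm, -ETA_CLAMP - offsets, lapack_driver="gelsd")
        mu, _ = _mu_from_beta(Xm, beta, offsets)
        return GeneFit(
            beta=beta, mu=mu, theta_used=theta,
            deviance=float(np.sum(gp_unit_deviance(y, mu, theta))),
            df_residual=n - p, iterations=0, converged=True,
            all_zero=True, clamped=True,
        )

    beta = np.asarray(init, dtype=float) if init is not None else initialize_beta(y, Xm, offsets)
    mu, lp = _mu_from_beta(Xm, beta, offsets)
    dev = float(np.sum(gp_unit_deviance(y, mu, theta)))
    trace = [dev]

    iterations = 0
    for iterations in range(1, MAX_ITER + 1):
        eta = lp - offsets
        w = mu / (1.0 + theta * mu)
        z = eta + (y - mu) / mu
        beta_prop = _wls(Xm, z, w)

        step = beta_prop - beta
        new_beta, new_mu, new_lp, new_dev = beta, mu, lp, dev
        scale = 1.0
        for _ in range(MAX_HALVINGS + 1):
            cand = beta + scale * step
            cmu, clp = _mu_from_beta(Xm, cand, offsets)
            cdev = float(np.sum(gp_unit_deviance(y, cmu, theta)))
            if np.isfinite(cdev) and cdev <= dev * (1 + 1e-14) + 1e-14:
                new_beta, new_mu, new_lp, new_dev = cand, cmu, clp, cdev
                break
            scale *= 0.5
        else:
            break  # no acceptable step; stop at current point

        rel_change = abs(dev - new_dev) / (abs(dev) + 0.1)
        beta, mu, lp, dev = new_beta, new_mu, new_lp, new_dev
        trace.append(dev)
        if rel_change < DEV_RTOL:
            break

    score = Xm.T @ ((y - mu) / (1.0 + theta * mu))
    converged = bool(np.max(np.abs(score)) <= 1e-6 * (1.0 + abs(y.sum())))
    clamped = bool(np.any(np.abs(lp) >= ETA_CLAMP - 1e-12))
    if np.max(np.abs(beta)) > BETA_CLAMP:
        converged = False  # divergence / separation: flagged, never raised

    return GeneFit(
        beta=beta, mu=mu, theta_used=theta,
        deviance=dev, df_residual=n - p,
        iterations=iterations, converged=converged,
        clamped=clamped, dev_trace=trace,
    )


def fit_all_genes(chunks, X, sf, theta_mode="estimate", theta_values=None,
                  cox_reid=True):
    """Fit every gene in a stream of gene-chunks; yields one fit per gene.

    ``theta_mode`` is ``"estimate"`` (alternating beta/theta maximum
    likelihood), ``"zero"`` (Poisson fast path) or ``"fixed-vector"``
    (``theta_values`` holds one theta per gene).  Output order equals input
    gene order and is invariant to the chunking.
    """
    from .dispersion import fit_gene  # deferred: dispersion imports fit_beta

    design = _as_design(X)
    offsets = np.log(np.asarray(sf.s if hasattr(sf, "s") else sf, dtype=float))
    gene_index = 0
    for chunk in chunks:
        chunk = np.asarray(chunk)
        if chunk.ndim != 2 or chunk.shape[1] != design.n_cells:
            raise ValueError(
                f"chunk has {chunk.shape} shape; expected (genes, {design.n_cells})"
            )
        for row in chunk:
            if theta_mode == "zero":
                fit = fit_beta(row, design, offsets, theta=0.0)
                theta_hat = 0.0
            elif theta_mode == "fixed-vector":
                th = float(np.asarray(theta_values)[gene_index])
                fit = fit_beta(row, design, offsets, theta=th)
                theta_hat = th
            elif theta_mode == "estimate":
                fit, theta_hat = fit_gene(row, design, offsets, cox_reid=cox_reid)
            else:
                raise ValueError(f"unknown theta_mode: {theta_mode!r}")
            yield fit, theta_hat
            gene_index += 1
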