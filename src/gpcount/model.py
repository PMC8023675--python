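"""Model/Results front end for Gamma-Poisson GLM inference.

:class:`GammaPoissonModel` bundles a count matrix (in memory or streamed
from disk), a design and size factors; :meth:`GammaPoissonModel.fit`
returns a :class:`GammaPoissonResults` carrying per-gene coefficient
estimates, overdispersions, deviances and convergence diagnostics, with
differential-expression testing (:meth:`GammaPoissonResults.test_de`) and a
``summary()`` table hanging off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignSpec, design_from_formula
from .dispersion import fit_trend
from .glm import fit_all_genes, fit_beta
from .io import MatrixHandle
from .preprocess import SizeFactors, estimate_size_factors
from .qltest import (
    bh_adjust,
    contrast_lfc,
    quasi_dispersion,
    shrink_quasi_dispersions,
    ql_f_test,
)

__all__ = ["GammaPoissonModel", "GammaPoissonResults"]


class GammaPoissonModel:
    """Gamma-Poisson GLM ``log mu = X beta + log s`` for a gene x cell
    count matrix.

    Parameters
    ----------
    counts : array (genes x cells) or :class:`~gpcount.io.MatrixHandle`
        Non-negative integer counts; a handle streams gene chunks so the
        matrix never has to be fully resident.
    design : :class:`~gpcount.design.DesignSpec` or array
        Full-rank cells x p design matrix.
    size_factors : str, array or :class:`~gpcount.preprocess.SizeFactors`
        ``"normed-sum"`` (default), ``"median-of-ratios"``, or explicit
        per-cell factors.
    """

    def __init__(self, counts, design, size_factors="normed-sum",
                 gene_names=None):
        if isinstance(counts, MatrixHandle):
            self.handle = counts
        else:
            self.handle = MatrixHandle(counts=np.asarray(counts))
        if gene_names is not None:
            self.handle.gene_names = list(map(str, gene_names))
        self.design = (
            design if isinstance(design, DesignSpec)
            else DesignSpec(np.asarray(design, dtype=float))
        )
        if self.design.n_cells != self.handle.n_cells:
            raise ValueError(
                f"design has {self.design.n_cells} rows but the matrix has "
                f"{self.handle.n_cells} cells"
            )
        self.size_factors = self._resolve_size_factors(size_factors)

    @classmethod
    def from_formula(cls, formula, metadata, counts, **kwargs):
        """Build the design from a one-sided formula over cell metadata."""
        design = design_from_formula(formula, metadata)
        return cls(counts, design, **kwargs)

    def _resolve_size_factors(self, spec) -> SizeFactors:
        if isinstance(spec, SizeFactors):
            if spec.s.shape[0] != self.handle.n_cells:
                raise ValueError("size factors must have one entry per cell")
            return spec
        if isinstance(spec, str):
            if spec == "normed-sum":
                # one streaming pass over column sums
                colsum = np.zeros(self.handle.n_cells, dtype=np.int64)
                for chunk in self.handle.iter_chunks():
                    colsum += chunk.sum(axis=0)
                zero = np.flatnonzero(colsum == 0)
                if zero.size:
                    raise ValueError(
                        f"cells with all-zero counts: indices {zero.tolist()}"
                    )
                s = colsum / np.exp(np.mean(np.log(colsum)))
                return SizeFactors(s, "normed-sum")
            if spec == "median-of-ratios":
                return estimate_size_factors(self.handle.to_array(), spec)
            raise ValueError(f"unknown size-factor method: {spec!r}")
        return estimate_size_factors(None, "user", user=np.asarray(spec, dtype=float))

    def fit(self, theta_mode="estimate", theta_values=None, cox_reid=True,
            chunk_size=None) -> "GammaPoissonResults":
        """Fit every gene; returns a :class:`GammaPoissonResults`.

        ``theta_mode`` is ``"estimate"`` (joint maximum likelihood, the
        default), ``"zero"`` (Poisson fast path) or ``"fixed-vector"``
        (``theta_values`` gives one overdispersion per gene).
        """
        chunks = self.handle.iter_chunks(chunk_size)
        rows = list(
            fit_all_genes(chunks, self.design, self.size_factors,
                          theta_mode=theta_mode, theta_values=theta_values,
                          cox_reid=cox_reid)
        )
        if len(rows) != self.handle.n_genes:
            raise ValueError(
                f"chunk stream produced {len(rows)} genes; expected "
                f"{self.handle.n_genes}"
            )
        fits = [f for f, _ in rows]
        return GammaPoissonResults(
            model=self,
            beta=np.array([f.beta for f in fits]),
            theta=np.array([t for _, t in rows]),
            deviance=np.array([f.deviance for f in fits]),
            df_residual=np.array([f.df_residual for f in fits]),
            mean_expression=np.array([f.mean_expression for f in fits]),
            converged=np.array([f.converged for f in fits]),
            all_zero=np.array([f.all_zero for f in fits]),
            clamped=np.array([f.clamped for f in fits]),
        )


class GammaPoissonResults:
    """Per-gene estimates from :meth:`GammaPoissonModel.fit`."""

    def __init__(self, model, beta, theta, deviance, df_residual,
                 mean_expression, converged, all_zero, clamped):
        self.model = model
        self.beta = beta
        self.theta = theta
        self.deviance = deviance
        self.df_residual = df_residual
        self.mean_expression = mean_expression
        self.converged = converged
        self.all_zero = all_zero
        self.clamped = clamped
        self._theta_trend = None

    @property
    def gene_names(self):
        return self.model.handle.gene_names

    @property
    def coef_names(self):
        return self.model.design.names

    def dispersion_trend(self) -> np.ndarray:
        """Trended overdispersion (running median over log mean expression)."""
        if self._theta_trend is None:
            self._theta_trend = fit_trend(self.theta, self.mean_expression)
        return self._theta_trend

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.beta, columns=[f"beta_{c}" for c in self.coef_names]
        )
        df.insert(0, "gene", self.gene_names)
        df["theta"] = self.theta
        df["deviance"] = self.deviance
        df["df_residual"] = self.df_residual
        df["mean_expression"] = self.mean_expression
        df["converged"] = self.converged.astype(int)
        df["all_zero"] = self.all_zero.astype(int)
        df["clamped"] = self.clamped.astype(int)
        return df

    def _resolve_contrast(self, contrast, dropped):
        p = len(self.coef_names)
        if contrast is None:
            if len(dropped) == 1:
                contrast = dropped[0]
            else:
                return None
        if isinstance(contrast, str):
            if contrast not in self.coef_names:
                raise ValueError(f"unknown coefficient: {contrast!r}")
            vec = np.zeros(p)
            vec[self.coef_names.index(contrast)] = 1.0
            return vec
        vec = np.asarray(contrast, dtype=float)
        if vec.shape != (p,):
            raise ValueError(f"contrast must have length {p}")
        return vec

    def test_de(self, reduced, contrast=None, use_gene_theta=False,
                chunk_size=None) -> pd.DataFrame:
        """Quasi-likelihood F-test of the full design against a nested
        reduced design.

        Parameters
        ----------
        reduced : list of coefficient names, formula string, or DesignSpec
            The null model; its column span must be contained in the full
            design's (names must be a subset when given as names).
        contrast : coefficient name or length-p vector, optional
            Contrast whose log2 fold change is reported; defaults to the
            single dropped coefficient when exactly one is dropped.
        use_gene_theta : bool
            Refit at the gene-wise theta instead of the trended theta.

        Returns a table with one row per gene: ``gene, lfc, F, df1, df2,
        pval, padj, converged``.
        """
        design = self.model.design
        if isinstance(reduced, DesignSpec):
            reduced_design = reduced
            dropped = [c for c in design.names if c not in reduced_design.names]
        elif isinstance(reduced, str):
            raise TypeError(
                "pass the reduced design as a list of coefficient names or a "
                "DesignSpec"
            )
        else:
            keep = list(reduced)
            missing = [c for c in keep if c not in design.names]
            if missing:
                raise ValueError(f"reduced design drops unknown columns: {missing}")
            reduced_design = design.subset(keep)
            dropped = [c for c in design.names if c not in keep]
        df1 = design.p - reduced_design.p
        if df1 < 0:
            raise ValueError("the reduced design has more coefficients than the full design")
        if reduced_design.n_cells != design.n_cells:
            raise ValueError("full and reduced designs must cover the same cells")

        theta_fit = self.theta if use_gene_theta else self.dispersion_trend()
        offsets = self.model.size_factors.log
        cvec = self._resolve_contrast(contrast, dropped)

        n = self.model.handle.n_genes
        dev_full = np.empty(n)
        dev_red = np.empty(n)
        lfc = np.full(n, np.nan)
        conv = np.zeros(n, dtype=bool)
        g = 0
        for chunk in self.model.handle.iter_chunks(chunk_size):
            for row in chunk:
                th = float(theta_fit[g])
                ff = fit_beta(row, design, offsets, theta=th)
                fr = fit_beta(row, reduced_design, offsets, theta=th)
                dev_full[g] = ff.deviance
                dev_red[g] = fr.deviance
                conv[g] = ff.converged and fr.converged
                if cvec is not None:
                    lfc[g] = contrast_lfc(ff.beta, cvec)
                g += 1

        df_res = self.df_residual.astype(float)
        testable = df_res >= 1
        F = np.full(n, np.nan)
        df2 = np.full(n, np.nan)
        pval = np.full(n, np.nan)
        if df1 == 0:
            # degenerate contrast: identical models, nothing to test
            F[testable], pval[testable] = 0.0, 1.0
            df2[testable] = np.inf
            df1 = 1  # reported denominator convention for the trivial test
            shrink = None
        else:
            sigma2 = quasi_dispersion(dev_full[testable], df_res[testable])
            shrink = shrink_quasi_dispersions(sigma2, df_res[testable])
            F_t, df2_t, p_t = ql_f_test(
                dev_full[testable], dev_red[testable], df1,
                df_res[testable], shrink.sigma2_shrunk, shrink.df_prior,
            )
            F[testable], df2[testable], pval[testable] = F_t, df2_t, p_t

        table = pd.DataFrame(
            {
                "gene": self.gene_names,
                "lfc": lfc,
                "F": F,
                "df1": float(df1),
                "df2": df2,
                "pval": pval,
                "padj": bh_adjust(pval),
                "converged": conv.astype(int),
            }
        )
        if shrink is not None:
            table.attrs["df_prior"] = shrink.df_prior
            table.attrs["sigma2_trend"] = shrink.sigma2_trend
        return table

    def summary(self, n_genes: int = 8) -> str:
        """Human-readable overview of the fit."""
        lines = [
            "Gamma-Poisson GLM fit",
            "=" * 52,
            f"genes: {len(self.gene_names)}    cells: {self.model.handle.n_cells}"
            f"    coefficients: {len(self.coef_names)}",
            f"design columns: {', '.join(self.coef_names)}",
            f"size factors: {self.model.size_factors.method}",
            f"converged: {int(self.converged.sum())}/{len(self.gene_names)}"
            f"    all-zero genes: {int(self.all_zero.sum())}",
            f"median theta: {float(np.median(self.theta)):.4g}"
            f"    median deviance/df: "
            f"{float(np.median(self.deviance / np.maximum(self.df_residual, 1))):.4g}",
            "-" * 52,
        ]
        head = self.to_frame().head(n_genes)
        lines.append(head.to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<GammaPoissonResults: {len(self.gene_names)} genes x "
            f"{len(self.coef_names)} coefficients>"
        )
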