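"""Size-factor estimation and pseudobulk aggregation.

Size factors model per-cell sequencing depth and enter the GLM only as
offsets ``log(s_c)`` on the linear predictor; counts are never divided.
Estimated factors are re-centered to geometric mean 1 so the intercept
keeps its interpretation as a typical-cell log expression level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SizeFactors", "estimate_size_factors", "pseudobulk", "PseudobulkSpec"]


@dataclass
class SizeFactors:
    s: np.ndarray  # positive, one per cell
    method: str  # "normed-sum" | "median-of-ratios" | "user"

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if np.any(~np.isfinite(self.s)) or np.any(self.s <= 0):
            raise ValueError("size factors must be positive and finite")

    @property
    def log(self) -> np.ndarray:
        return np.log(self.s)


def _recenter(s: np.ndarray) -> np.ndarray:
    return s / np.exp(np.mean(np.log(s)))


def estimate_size_factors(counts, method: str = "normed-sum", user=None) -> SizeFactors:
    """Estimate per-cell size factors from a gene x cell count matrix.

    Methods
    -------
    ``"normed-sum"`` (default)
        Column sums, re-centered to geometric mean 1.  Robust in the
        many-zero single-cell regime.
    ``"median-of-ratios"``
        Per cell, the median over reference genes (genes with all-positive
        counts) of ``count / geometric-mean(gene)``, re-centered.  Falls back
        to normed-sum with a warning when no gene is all-positive.
    ``"user"``
        ``user`` passed through unchanged after a positivity check.
    """
    if method == "user":
        if user is None:
            raise ValueError("method='user' requires a size-factor vector")
        return SizeFactors(np.asarray(user, dtype=float), "user")

    counts = np.asarray(counts)
    colsum = counts.sum(axis=0).astype(float)
    zero_cells = np.flatnonzero(colsum == 0)
    if zero_cells.size:
        raise ValueError(
            f"cells with all-zero counts cannot be normalized: indices {zero_cells.tolist()}"
        )

    if method == "normed-sum":
        return SizeFactors(_recenter(colsum), "normed-sum")

    if method == "median-of-ratios":
        allpos = np.all(counts > 0, axis=1)
        if not np.any(allpos):
            warnings.warn(
                "median-of-ratios undefined (no gene has all-positive counts); "
                "falling back to normed-sum",
                stacklevel=2,
            )
            return SizeFactors(_recenter(colsum), "normed-sum")
        ref = counts[allpos].astype(float)
        geo = np.exp(np.mean(np.log(ref), axis=1))  # per-gene geometric mean
        s = np.median(ref / geo[:, None], axis=0)
        return SizeFactors(_recenter(s), "median-of-ratios")

    raise ValueError(f"unknown size-factor method: {method!r}")


@dataclass
class PseudobulkSpec:
    """Counts and covariates aggregated to one column per sample label."""

    counts: np.ndarray  # gene x sample, exact integer sums
    labels: list  # sample order = first appearance of labels
    design_covariates: pd.DataFrame  # one row per label
    cell_labels: np.ndarray


def pseudobulk(counts, grouping, design_covariates=None) -> PseudobulkSpec:
    """Sum counts within sample labels, carrying the per-sample covariates.

    ``grouping`` assigns one sample label per cell; every design covariate
    must be constant within a label (an error names the offending label and
    covariate otherwise).  Sums are exact integer sums; sample order is the
    order in which labels first appear.
    """
    counts = np.asarray(counts)
    grouping = np.asarray(grouping)
    if grouping.shape[0] != counts.shape[1]:
        raise ValueError("grouping must assign a label to every cell")

    labels = list(pd.unique(grouping))
    agg = np.zeros((counts.shape[0], len(labels)), dtype=np.int64)
    for k, lab in enumerate(labels):
        agg[:, k] = counts[:, grouping == lab].sum(axis=1)

    if design_covariates is not None:
        df = pd.DataFrame(design_covariates).reset_index(drop=True)
        rows = []
        for lab in labels:
            block = df[grouping == lab]
            for col in df.columns:
                if block[col].nunique(dropna=False) > 1:
                    raise ValueError(
                        f"covariate {col!r} varies within pseudobulk label {lab!r}"
                    )
            rows.append(block.iloc[0])
        agg_design = pd.DataFrame(rows).reset_index(drop=True)
        agg_design.index = pd.Index(labels, name="sample")
    else:
        agg_design = pd.DataFrame(index=pd.Index(labels, name="sample"))

    return PseudobulkSpec(agg, labels, agg_design, grouping)
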