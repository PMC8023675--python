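"""Design matrices: validated full-rank specs and a small one-sided formula
builder over cell metadata (treatment coding, reference = first level seen)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["DesignSpec", "design_from_formula", "design_from_tsv"]


@dataclass
class DesignSpec:
    """A cells x p design matrix with column names, validated full rank.

    Raises ``ValueError`` listing the collinear columns if rank-deficient,
    or if there are not more rows than columns (at least one residual
    degree of freedom is required downstream).
    """

    X: np.ndarray
    names: list[str] = field(default=None)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        n, p = self.X.shape
        if self.names is None:
            self.names = [f"x{j}" for j in range(p)]
        self.names = list(map(str, self.names))
        if len(self.names) != p:
            raise ValueError("number of column names must match design columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite values")
        if p >= n:
            raise ValueError(
                f"design has {p} coefficients for {n} cells; residual "
                "degrees of freedom must be >= 1"
            )
        # rank-revealing pivoted QR; dependent columns are the pivots past rank
        _, R, piv = linalg.qr(self.X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
        rank = int(np.sum(diag > tol))
        if rank < p:
            bad = sorted(self.names[j] for j in piv[rank:])
            raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
        self.rank = rank

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, names) -> "DesignSpec":
        """Reduced design keeping only the named columns (order preserved)."""
        names = list(names)
        missing = [c for c in names if c not in self.names]
        if missing:
            raise ValueError(f"columns not in design: {missing}")
        idx = [self.names.index(c) for c in names]
        return DesignSpec(self.X[:, idx], [self.names[i] for i in idx])


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col) or isinstance(
        col.dtype, pd.CategoricalDtype
    )


def design_from_formula(formula: str, metadata: pd.DataFrame) -> DesignSpec:
    """Build a treatment-coded design from a one-sided formula.

    ``formula`` is ``"~ term + term + ..."`` (the leading ``~`` is optional).
    Categorical terms are dummy-coded with the first level observed as the
    reference; numeric terms enter as-is.  ``0`` or ``-1`` as a term removes
    the intercept.
    """
    body = formula.strip()
    if body.startswith("~"):
        body = body[1:]
    terms = [t.strip() for t in body.split("+") if t.strip()]
    intercept = True
    cols, names = [], []
    for term in terms:
        if term in ("0", "-1"):
            intercept = False
            continue
        if term == "1":
            continue
        if term not in metadata.columns:
            raise ValueError(f"formula term {term!r} not found in metadata columns")
        col = metadata[term]
        if _is_categorical(col):
            levels = list(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    if intercept:
        cols.insert(0, np.ones(len(metadata)))
        names.insert(0, "Intercept")
    if not cols:
        raise ValueError("formula produced an empty design")
    return DesignSpec(np.column_stack(cols), names)


def design_from_tsv(path) -> DesignSpec:
    """Read a design matrix from a TSV whose header row names the coefficients.

    A first column named ``cell``/``barcode`` (or an unnamed index column)
    is treated as row labels, not a coefficient.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    first = df.columns[0]
    if first.lower() in ("cell", "barcode", "cell_id", "") or first.startswith(
        "Unnamed"
    ):
        df = df.set_index(first)
    return DesignSpec(df.to_numpy(dtype=float), list(df.columns))
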