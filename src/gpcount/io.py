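"""Count-matrix readers/writers and gene-chunk streaming.

Genes are independent given the design and size factors, so fitting streams
over contiguous gene blocks; the on-disk backend (10x-style HDF5, CSC with
genes as the first shape dimension) defers block reads until iteration so
the full matrix never has to be resident.  Supported formats:

- MatrixMarket ``.mtx`` (coordinate, integer, 1-based, general) with
  optional sidecar name files,
- 10x-style HDF5 (``matrix`` group with data/indices/indptr/shape and
  feature/barcode names; a flat root-level layout is accepted on read),
- dense TSV (gene rows, header = cell names) for small inputs.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "MatrixHandle",
    "read_matrix",
    "iter_chunks",
    "write_mtx",
    "write_10x_h5",
    "write_results",
]

DEFAULT_CHUNK_SIZE = 1000


class MatrixHandle:
    """Uniform access to a gene x cell count matrix, in memory or on disk.

    Iteration with :meth:`iter_chunks` yields contiguous gene blocks as
    dense int64 arrays (genes x cells) covering every gene exactly once, in
    order.  The on-disk backend keeps only one gene block (plus a bounded
    cell-column buffer) resident at a time.
    """

    def __init__(self, *, counts=None, h5_path=None, gene_names=None,
                 cell_names=None, chunk_size=DEFAULT_CHUNK_SIZE):
        if (counts is None) == (h5_path is None):
            raise ValueError("exactly one of counts / h5_path must be given")
        self._counts = None
        self._h5_path = None
        if counts is not None:
            self._counts = np.asarray(counts)
            _validate_counts(self._counts)
            n_genes, n_cells = self._counts.shape
            self.backend = "in-memory"
        else:
            self._h5_path = str(h5_path)
            n_genes, n_cells, h5_genes, h5_cells = _h5_dims_and_names(self._h5_path)
            gene_names = gene_names if gene_names is not None else h5_genes
            cell_names = cell_names if cell_names is not None else h5_cells
            self.backend = "on-disk"
        self.n_genes, self.n_cells = int(n_genes), int(n_cells)
        self.gene_names = _default_names(gene_names, self.n_genes, "gene")
        self.cell_names = _default_names(cell_names, self.n_cells, "cell")
        if len(set(self.gene_names)) != self.n_genes:
            raise ValueError("gene names are not unique")
        if len(set(self.cell_names)) != self.n_cells:
            raise ValueError("cell names are not unique")
        self.chunk_size = int(chunk_size)

    def iter_chunks(self, chunk_size=None):
        chunk_size = int(chunk_size or self.chunk_size)
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.backend == "in-memory":
            for g0 in range(0, self.n_genes, chunk_size):
                yield np.asarray(
                    self._counts[g0 : g0 + chunk_size], dtype=np.int64
                )
        else:
            yield from _iter_h5_chunks(self._h5_path, self.n_genes,
                                       self.n_cells, chunk_size)

    def to_array(self) -> np.ndarray:
        """Materialize the full matrix (small inputs / tests only)."""
        if self.backend == "in-memory":
            return np.asarray(self._counts, dtype=np.int64)
        return np.concatenate(list(self.iter_chunks(self.n_genes or 1)), axis=0)


def iter_chunks(handle: MatrixHandle, chunk_size: int):
    """Stream contiguous gene blocks from a handle (module-level alias)."""
    return handle.iter_chunks(chunk_size)


def _default_names(names, n, prefix):
    if names is None:
        width = max(4, len(str(n)))
        return [f"{prefix}_{i + 1:0{width}d}" for i in range(n)]
    names = [str(x) for x in names]
    if len(names) != n:
        raise ValueError(
            f"{len(names)} {prefix} names for a matrix with {n} {prefix}s"
        )
    return names


def _validate_counts(arr):
    if arr.ndim != 2:
        raise ValueError("count matrix must be 2-dimensional (genes x cells)")
    if np.issubdtype(arr.dtype, np.floating):
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            g, c = bad[0]
            raise ValueError(
                f"counts must be non-negative integers; offending entry at "
                f"(gene {g}, cell {c}) = {arr[g, c]}"
            )
    elif np.issubdtype(arr.dtype, np.integer):
        bad = np.argwhere(arr < 0)
        if bad.size:
            g, c = bad[0]
            raise ValueError(
                f"counts must be non-negative; offending entry at "
                f"(gene {g}, cell {c}) = {arr[g, c]}"
            )
    else:
        raise ValueError(f"unsupported count dtype {arr.dtype}")


# ---------------------------------------------------------------- readers

def read_matrix(path, format=None, on_disk=False,
                chunk_size=DEFAULT_CHUNK_SIZE) -> MatrixHandle:
    """Read a gene x cell count matrix.

    ``format`` is ``"mtx"``, ``"10x-h5"`` or ``"tsv"``; inferred from the
    suffix when omitted.  ``on_disk=True`` keeps an HDF5 matrix on disk and
    streams it at iteration time (only supported for ``10x-h5``; convert
    other formats with :func:`write_10x_h5` first).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".h5": "10x-h5", ".hdf5": "10x-h5",
                  ".tsv": "tsv", ".txt": "tsv"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx":
        if on_disk:
            raise ValueError(
                "on-disk access requires the 10x-h5 format; convert with write_10x_h5"
            )
        mat = spio.mmread(path)
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        _validate_counts(dense)
        genes, cells = _read_mtx_sidecars(path, dense.shape)
        return MatrixHandle(counts=dense.astype(np.int64), gene_names=genes,
                            cell_names=cells, chunk_size=chunk_size)

    if format == "tsv":
        if on_disk:
            raise ValueError(
                "on-disk access requires the 10x-h5 format; convert with write_10x_h5"
            )
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        _validate_counts(df.to_numpy())
        return MatrixHandle(counts=df.to_numpy().astype(np.int64),
                            gene_names=list(df.index.astype(str)),
                            cell_names=list(df.columns.astype(str)),
                            chunk_size=chunk_size)

    if format == "10x-h5":
        if on_disk:
            return MatrixHandle(h5_path=path, chunk_size=chunk_size)
        handle = MatrixHandle(h5_path=path, chunk_size=chunk_size)
        return MatrixHandle(counts=handle.to_array(),
                            gene_names=handle.gene_names,
                            cell_names=handle.cell_names,
                            chunk_size=chunk_size)

    raise ValueError(f"unknown format: {format!r}")


def _read_mtx_sidecars(path: Path, shape):
    """Look for feature/barcode name files next to an .mtx matrix."""
    stem = path.with_suffix("")
    gene_candidates = [Path(str(stem) + ".features.txt"),
                       path.parent / "features.tsv", path.parent / "genes.tsv"]
    cell_candidates = [Path(str(stem) + ".barcodes.txt"),
                       path.parent / "barcodes.tsv"]

    def load(candidates, n, what):
        for cand in candidates:
            if cand.exists():
                names = [
                    line.split("\t")[0]
                    for line in cand.read_text().splitlines()
                    if line.strip()
                ]
                if len(names) != n:
                    raise ValueError(
                        f"{cand} has {len(names)} {what} names but the matrix "
                        f"has {n} {what}s"
                    )
                return names
        return None

    return load(gene_candidates, shape[0], "gene"), load(cell_candidates, shape[1], "cell")


def _open_h5_group(f):
    """Return (group, gene_names, cell_names) for v2/v3 or flat layouts."""
    if "matrix" in f:
        g = f["matrix"]
        genes = cells = None
        if "features" in g and "id" in g["features"]:
            genes = [x.decode() if isinstance(x, bytes) else str(x)
                     for x in g["features"]["id"][:]]
        elif "genes" in g:
            genes = [x.decode() if isinstance(x, bytes) else str(x)
                     for x in g["genes"][:]]
        if "barcodes" in g:
            cells = [x.decode() if isinstance(x, bytes) else str(x)
                     for x in g["barcodes"][:]]
        return g, genes, cells
    if all(k in f for k in ("data", "indices", "indptr", "shape")):
        genes = cells = None
        if "genes" in f:
            genes = [x.decode() if isinstance(x, bytes) else str(x)
                     for x in f["genes"][:]]
        if "barcodes" in f:
            cells = [x.decode() if isinstance(x, bytes) else str(x)
                     for x in f["barcodes"][:]]
        return f, genes, cells
    raise ValueError("HDF5 file has neither a 'matrix' group nor a flat CSC layout")


def _h5_dims_and_names(path):
    import h5py

    with h5py.File(path, "r") as f:
        g, genes, cells = _open_h5_group(f)
        shape = tuple(int(x) for x in g["shape"][:])
    return shape[0], shape[1], genes, cells


def _iter_h5_chunks(path, n_genes, n_cells, chunk_size,
                    cell_block: int = 4096):
    """Yield dense gene blocks from a CSC (genes x cells) HDF5 matrix,
    reading cell columns in bounded blocks."""
    import h5py

    with h5py.File(path, "r") as f:
        g, _, _ = _open_h5_group(f)
        indptr = g["indptr"][:]
        data_ds, idx_ds = g["data"], g["indices"]
        for g0 in range(0, n_genes, chunk_size):
            g1 = min(g0 + chunk_size, n_genes)
            block = np.zeros((g1 - g0, n_cells), dtype=np.int64)
            for c0 in range(0, n_cells, cell_block):
                c1 = min(c0 + cell_block, n_cells)
                lo, hi = int(indptr[c0]), int(indptr[c1])
                if hi == lo:
                    continue
                data = np.asarray(data_ds[lo:hi])
                rows = np.asarray(idx_ds[lo:hi])
                cols = np.repeat(
                    np.arange(c0, c1), np.diff(indptr[c0 : c1 + 1]).astype(int)
                )
                keep = (rows >= g0) & (rows < g1)
                if np.any(data[keep] != np.floor(data[keep])) or np.any(data[keep] < 0):
                    raise ValueError("HDF5 counts must be non-negative integers")
                block[rows[keep] - g0, cols[keep]] = data[keep].astype(np.int64)
            yield block


# ---------------------------------------------------------------- writers

def write_mtx(path, counts, gene_names=None, cell_names=None):
    """Write counts as MatrixMarket coordinate/integer with sidecar names."""
    path = Path(path)
    counts = np.asarray(counts)
    _validate_counts(counts)
    spio.mmwrite(path, sparse.coo_matrix(counts.astype(np.int64)),
                 field="integer")
    stem = path.with_suffix("")
    if gene_names is not None:
        Path(str(stem) + ".features.txt").write_text("\n".join(gene_names) + "\n")
    if cell_names is not None:
        Path(str(stem) + ".barcodes.txt").write_text("\n".join(cell_names) + "\n")


def write_10x_h5(path, counts, gene_names=None, cell_names=None):
    """Write counts as a 10x-v3-style HDF5 group (CSC, genes x cells).

    Dataset timestamps are disabled so identical inputs produce
    byte-identical files.
    """
    import h5py

    counts = np.asarray(counts)
    _validate_counts(counts)
    n_genes, n_cells = counts.shape
    gene_names = _default_names(gene_names, n_genes, "gene")
    cell_names = _default_names(cell_names, n_cells, "cell")
    csc = sparse.csc_matrix(counts.astype(np.int64))
    str_dt = "S64"
    with h5py.File(path, "w", track_order=False) as f:
        g = f.create_group("matrix", track_order=False)

        def ds(group, name, data):
            group.create_dataset(name, data=data, track_times=False)

        ds(g, "data", csc.data.astype(np.int64))
        ds(g, "indices", csc.indices.astype(np.int64))
        ds(g, "indptr", csc.indptr.astype(np.int64))
        ds(g, "shape", np.array([n_genes, n_cells], dtype=np.int64))
        ds(g, "barcodes", np.array(cell_names, dtype=str_dt))
        feat = g.create_group("features", track_order=False)
        ds(feat, "id", np.array(gene_names, dtype=str_dt))
        ds(feat, "name", np.array(gene_names, dtype=str_dt))
        ds(feat, "feature_type", np.array([b"Gene Expression"] * n_genes, dtype=str_dt))


def write_results(table: pd.DataFrame, path, header_lines=None):
    """Write a results table as deterministic TSV.

    Fixed column order (as given), floats formatted ``%.6g``, missing
    values as ``NA``; byte-identical across runs on identical inputs.
    Optional ``header_lines`` are emitted first as ``#``-prefixed comments.
    """
    path = Path(path)
    try:
        with open(path, "w", newline="\n") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            table.to_csv(fh, sep="\t", index=False, na_rep="NA",
                         float_format="%.6g", lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
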