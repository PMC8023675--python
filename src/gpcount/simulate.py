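"""Synthetic Gamma-Poisson count data with known ground truth.

Counts are drawn hierarchically — a Gamma-distributed rate with mean mu and
shape 1/theta, then Poisson — so the marginal is Gamma-Poisson with
variance mu + theta*mu**2; theta = 0 draws Poisson directly.  One global
integer seed determines everything; each gene consumes its own
counter-derived random stream, so changing the number of genes or their
order never changes any other gene's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec
from .io import write_10x_h5, write_mtx

__all__ = ["SimConfig", "simulate_counts", "simulate_two_group", "make_fixture_suite"]


@dataclass
class SimConfig:
    """Recipe for a simulated gene x cell Gamma-Poisson count matrix."""

    n_genes: int
    n_cells: int
    beta: np.ndarray  # genes x p
    design: np.ndarray  # cells x p
    theta: object = 0.0  # scalar, per-gene vector, or callable of mean
    sf_log_sd: float = 0.0  # log-normal sd of size factors (0 = all 1)
    seed: int = 0
    design_names: list = field(default=None)


def _gene_rng(seed: int, gene: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene,)))


def _sf_rng(seed: int) -> np.random.Generator:
    # dedicated stream so size factors are independent of every gene stream
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1 << 20,)))


def _draw_gp(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    if theta == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / theta
    rate = rng.gamma(shape, theta * mu)  # mean mu, var theta*mu^2
    return rng.poisson(rate)


def simulate_counts(config: SimConfig):
    """Draw counts under ``mu_gc = sf_c * exp((X beta_g)_c)``.

    Returns ``(counts, X, sf, truth)`` where ``truth`` is a dict holding
    the generating ``beta`` (genes x p), per-gene ``theta`` and ``sf``.
    """
    beta = np.atleast_2d(np.asarray(config.beta, dtype=float))
    X = np.asarray(config.design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if beta.shape != (config.n_genes, X.shape[1]):
        raise ValueError(
            f"beta must be (n_genes, p) = ({config.n_genes}, {X.shape[1]}); "
            f"got {beta.shape}"
        )
    if X.shape[0] != config.n_cells:
        raise ValueError("design rows must equal n_cells")
    if config.sf_log_sd < 0:
        raise ValueError("sf_log_sd must be non-negative")

    if config.sf_log_sd > 0:
        sf = np.exp(_sf_rng(config.seed).normal(0.0, config.sf_log_sd, config.n_cells))
        sf /= np.exp(np.mean(np.log(sf)))
    else:
        sf = np.ones(config.n_cells)

    base_mu = np.exp(beta @ X.T)  # genes x cells, before size factors
    if callable(config.theta):
        theta = np.array([float(config.theta(m)) for m in base_mu.mean(axis=1)])
    else:
        theta = np.broadcast_to(
            np.asarray(config.theta, dtype=float), (config.n_genes,)
        ).copy()
    if np.any(theta < 0):
        raise ValueError("theta must be non-negative")

    counts = np.empty((config.n_genes, config.n_cells), dtype=np.int64)
    for g in range(config.n_genes):
        rng = _gene_rng(config.seed, g)
        counts[g] = _draw_gp(rng, sf * base_mu[g], float(theta[g]))

    truth = {"beta": beta, "theta": theta, "sf": sf}
    return counts, X, sf, truth


def simulate_two_group(n_genes, n_cells, seed, theta=0.4, frac_de=0.0,
                       lfc=0.0, base_mean_range=(5.0, 50.0), sf_log_sd=0.0):
    """Two balanced groups; a fraction ``frac_de`` of genes carries a
    log2 fold change ``lfc`` in the second group.

    Baseline means are log-uniform over ``base_mean_range``.  Returns
    ``(counts, design, sf, truth)`` with ``truth['is_de']`` marking the
    non-null genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1 << 21,)))
    half = n_cells // 2
    group = np.zeros(n_cells)
    group[half:] = 1.0
    X = np.column_stack([np.ones(n_cells), group])

    lo, hi = base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    n_de = int(round(frac_de * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de:
        is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    beta = np.column_stack([np.log(base),
                            np.where(is_de, lfc * np.log(2.0), 0.0)])

    cfg = SimConfig(n_genes=n_genes, n_cells=n_cells, beta=beta, design=X,
                    theta=theta, sf_log_sd=sf_log_sd, seed=seed,
                    design_names=["Intercept", "group[1]"])
    counts, X, sf, truth = simulate_counts(cfg)
    truth["is_de"] = is_de
    design = DesignSpec(X, ["Intercept", "group[1]"])
    return counts, design, sf, truth


FIXTURE_MANIFEST = [
    "small.mtx", "small.features.txt", "small.barcodes.txt",
    "small_10x.h5",
    "de_counts.tsv", "de_metadata.tsv", "de_truth.tsv",
    "null_counts.tsv", "null_metadata.tsv", "null_truth.tsv",
]


def make_fixture_suite(out_dir, seed: int = 0) -> list:
    """Write the canonical cross-module fixtures; returns the file list.

    Contents: a small matrix as MatrixMarket and as 10x-style HDF5; a
    two-group differential-expression matrix (10% non-null genes at log2
    fold change 1) and a matched null matrix, each as TSV with a truth
    table.  Fully deterministic in ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # small matrix: 20 genes x 12 cells, intercept-only, moderate dispersion
    n_g, n_c = 20, 12
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1 << 22,)))
    beta = np.log(np.exp(rng.uniform(np.log(2.0), np.log(30.0), n_g)))[:, None]
    cfg = SimConfig(n_genes=n_g, n_cells=n_c, beta=beta,
                    design=np.ones((n_c, 1)), theta=0.3, sf_log_sd=0.2, seed=seed)
    counts, _, _, _ = simulate_counts(cfg)
    genes = [f"gene_{i + 1:04d}" for i in range(n_g)]
    cells = [f"cell_{i + 1:04d}" for i in range(n_c)]
    write_mtx(out / "small.mtx", counts, genes, cells)
    write_10x_h5(out / "small_10x.h5", counts, genes, cells)

    def dump(name, counts, truth, n_cells, extra_truth=None):
        genes = [f"gene_{i + 1:04d}" for i in range(counts.shape[0])]
        cells = [f"cell_{i + 1:04d}" for i in range(n_cells)]
        df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cells)
        df.to_csv(out / f"{name}_counts.tsv", sep="\t", lineterminator="\n")
        half = n_cells // 2
        meta = pd.DataFrame(
            {"cell": cells, "group": ["a"] * half + ["b"] * (n_cells - half)}
        )
        meta.to_csv(out / f"{name}_metadata.tsv", sep="\t", index=False,
                    lineterminator="\n")
        tr = pd.DataFrame(
            {
                "gene": genes,
                "beta_intercept": truth["beta"][:, 0],
                "beta_group": truth["beta"][:, 1],
                "theta": truth["theta"],
            }
        )
        if extra_truth is not None:
            for k, v in extra_truth.items():
                tr[k] = v
        tr.to_csv(out / f"{name}_truth.tsv", sep="\t", index=False,
                  float_format="%.10g", lineterminator="\n")

    n_cells = 60
    counts_de, _, _, truth_de = simulate_two_group(
        120, n_cells, seed=seed + 1, theta=0.3, frac_de=0.10, lfc=1.0
    )
    dump("de", counts_de, truth_de, n_cells,
         {"is_de": truth_de["is_de"].astype(int)})

    counts_null, _, _, truth_null = simulate_two_group(
        120, n_cells, seed=seed + 2, theta=0.3, frac_de=0.0, lfc=0.0
    )
    dump("null", counts_null, truth_null, n_cells)

    return sorted(p.name for p in out.iterdir())
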